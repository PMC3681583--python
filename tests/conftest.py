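import numpy as np
import pytest

from pcov.datamodel import TraitTable


@pytest.fixture
def small_table() -> TraitTable:
    """Three individuals, two traits, hand-checkable covariance."""
    return TraitTable(
        species="Amphiprion akindynos",
        population="LZI",
        margin_status="NB",
        trait_names=("CPD", "DFL"),
        values=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
    )
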