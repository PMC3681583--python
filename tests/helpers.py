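"""Shared builders for synthetic test inputs."""

import numpy as np

from pcov.datamodel import CANONICAL_TRAITS, TraitTable


def random_table(p: int, m: int, seed: int, species: str = "Amphiprion akindynos",
                 population: str = "LZI", margin: str = "C") -> TraitTable:
    """Positive random trait table with mild correlation structure."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, p)) / np.sqrt(p)
    base = rng.normal(size=(m, p))
    values = 30.0 + base @ a.T + rng.normal(size=(m, p))
    values = np.abs(values) + 0.1
    return TraitTable(
        species=species,
        population=population,
        margin_status=margin,
        trait_names=CANONICAL_TRAITS[:p],
        values=values,
    )
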