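"""Study design: congeneric central/marginal population contrasts.

The comparative design pairs, within each genus, a focal species with a
population at a geographic range border against a congeneric control species
whose two sampled populations both sit well inside its range.  Both members
of a pair are sampled at the same two sites, so site-environment effects on
the phenotypic covariance matrix cancel in the contrast.

:data:`REFERENCE_STUDY` encodes the Great Barrier Reef reef-fish design this
package was written around: six species x two sites (Lizard Island "LZI" in
the north, One Tree Island "OTI" in the south), with per-genus trait subsets
and per-population sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datamodel import GENUS_TRAIT_DROPS, TraitTable, ValidationError


@dataclass(frozen=True)
class SpeciesDesign:
    """One species' two sampled populations and its range metadata."""

    species: str
    #: site label -> margin status ("C", "NB" or "SB") of that population
    populations: dict[str, str]
    #: degrees latitude of the northern and southern range limits
    north_limit: float | None = None
    south_limit: float | None = None
    #: per-population sample sizes, site label -> M
    sample_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def is_focal(self) -> bool:
        """True if one of the populations sits at a range border."""
        return any(status in ("NB", "SB") for status in self.populations.values())

    @property
    def range_size(self) -> float | None:
        """North-south range extent in degrees latitude."""
        if self.north_limit is None or self.south_limit is None:
            return None
        return self.north_limit - self.south_limit


@dataclass(frozen=True)
class Contrast:
    """A congeneric pair: focal species (with a border population) vs control."""

    focal: SpeciesDesign
    control: SpeciesDesign

    def __post_init__(self) -> None:
        if self.focal.genus != self.control.genus:
            raise ValidationError(
                f"contrast species must share a genus: "
                f"{self.focal.species} vs {self.control.species}"
            )
        if not self.focal.is_focal or self.control.is_focal:
            raise ValidationError(
                "focal species needs a border population and the control must not"
            )


@dataclass(frozen=True)
class StudyDesign:
    """A set of congeneric contrasts sharing two sampling sites."""

    contrasts: tuple[Contrast, ...]
    north_site: str = "LZI"
    south_site: str = "OTI"

    @property
    def species(self) -> tuple[SpeciesDesign, ...]:
        out: list[SpeciesDesign] = []
        for c in self.contrasts:
            out.extend((c.focal, c.control))
        return tuple(out)

    @property
    def sites(self) -> tuple[str, str]:
        return (self.north_site, self.south_site)

    def species_design(self, name: str) -> SpeciesDesign:
        for sp in self.species:
            if sp.species == name:
                return sp
        raise ValidationError(f"species {name!r} not in design")

    def trait_count(self, species: str) -> int:
        genus = self.species_design(species).genus
        return 9 - len(GENUS_TRAIT_DROPS[genus])

    def validate_tables(
        self, tables: dict[tuple[str, str], TraitTable]
    ) -> None:
        """Check that every species-site combination has a consistent table."""
        for sp in self.species:
            for site, status in sp.populations.items():
                key = (sp.species, site)
                if key not in tables:
                    raise ValidationError(f"missing table for {sp.species} at {site}")
                t = tables[key]
                if t.margin_status != status:
                    raise ValidationError(
                        f"{sp.species} at {site}: margin status {t.margin_status!r} "
                        f"does not match design {status!r}"
                    )


def _sp(
    name: str,
    statuses: tuple[str, str],
    north: float,
    south: float,
    sizes: tuple[int, int],
) -> SpeciesDesign:
    return SpeciesDesign(
        species=name,
        populations={"LZI": statuses[0], "OTI": statuses[1]},
        north_limit=north,
        south_limit=south,
        sample_sizes={"LZI": sizes[0], "OTI": sizes[1]},
    )


#: The six-species reef-fish design: (LZI status, OTI status), range limits in
#: degrees latitude (positive north), and (LZI, OTI) sample sizes.
REFERENCE_STUDY = StudyDesign(
    contrasts=(
        Contrast(
            focal=_sp("Amblygobius rainfordi", ("C", "SB"), 9.0, -24.0, (65, 47)),
            control=_sp("Amblygobius phalaena", ("C", "C"), 25.0, -34.0, (66, 69)),
        ),
        Contrast(
            focal=_sp("Amphiprion akindynos", ("NB", "C"), -11.0, -33.0, (53, 76)),
            control=_sp("Amphiprion melanopus", ("C", "C"), 20.0, -33.0, (47, 67)),
        ),
        Contrast(
            focal=_sp("Chrysiptera rollandi", ("C", "SB"), 14.0, -24.0, (56, 69)),
            control=_sp("Chrysiptera rex", ("C", "C"), 24.0, -33.0, (80, 76)),
        ),
    ),
)
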