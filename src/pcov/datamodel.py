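"""Trait tables, covariance estimates, and tabular I/O.

The raw input of every analysis in this package is a table of linear
morphological measurements (mm) on individual fish, labelled with species,
population (site) and range-margin status.  From such a table the package
computes the phenotypic variance-covariance matrix **P** of a population,
the object that all downstream comparisons operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical trait codes, in canonical order: minimum caudal peduncle depth,
#: dorsal fin length, nape length, head length, eye diameter, body depth at
#: the back of the head, pectoral fin depth, inter pelvic/anal fin distance,
#: anal fin length.
CANONICAL_TRAITS: tuple[str, ...] = (
    "CPD", "DFL", "NPL", "HDL", "EYD", "BDH", "PFD", "IPA", "AFL",
)

#: Traits dropped per genus because they could not be measured reliably.
GENUS_TRAIT_DROPS: dict[str, tuple[str, ...]] = {
    "Amphiprion": (),
    "Chrysiptera": ("NPL", "HDL"),
    "Amblygobius": ("HDL", "EYD", "PFD"),
}

MARGIN_CODES = ("C", "NB", "SB")  # central / northern border / southern border

#: Metadata columns expected before the trait columns in input files.
META_COLUMNS = ("individual_id", "species", "population", "margin_status")


class ValidationError(ValueError):
    """Raised when an input table violates the trait-table contract."""


@dataclass(frozen=True)
class TraitTable:
    """Measurements of ``M`` individuals on ``N`` named traits for one population.

    Parameters
    ----------
    species, population
        Labels; ``population`` is a site code such as ``"LZI"`` or ``"OTI"``.
    margin_status
        ``"C"`` (central), ``"NB"`` (northern border) or ``"SB"`` (southern
        border) for this population of this species.
    trait_names
        Ordered trait labels, a subset of :data:`CANONICAL_TRAITS`.
    values
        ``(M, N)`` array of strictly positive measurements in mm.
    individual_ids
        Optional per-row identifiers; generated if omitted.
    """

    species: str
    population: str
    margin_status: str
    trait_names: tuple[str, ...]
    values: np.ndarray
    individual_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        if self.margin_status not in MARGIN_CODES:
            raise ValidationError(
                f"margin_status {self.margin_status!r} not one of {MARGIN_CODES}"
            )
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D individuals x traits array")
        m, n = values.shape
        if len(self.trait_names) != n:
            raise ValidationError(
                f"{len(self.trait_names)} trait names for {n} value columns"
            )
        if len(set(self.trait_names)) != n:
            raise ValidationError("trait names must be unique")
        unknown = [t for t in self.trait_names if t not in CANONICAL_TRAITS]
        if unknown:
            raise ValidationError(
                f"unknown trait name(s) {unknown}; allowed: {list(CANONICAL_TRAITS)}"
            )
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"missing value, row {r + 1}, trait {self.trait_names[c]}"
            )
        nonpos = np.argwhere(values <= 0)
        if nonpos.size:
            r, c = nonpos[0]
            raise ValidationError(
                f"non-positive measurement {values[r, c]!r}, row {r + 1}, "
                f"trait {self.trait_names[c]}"
            )
        if m < n + 1:
            raise ValidationError(
                f"need at least N+1={n + 1} individuals for {n} traits, got {m}"
            )
        if not self.individual_ids:
            object.__setattr__(
                self, "individual_ids", tuple(f"ind{i + 1}" for i in range(m))
            )
        elif len(self.individual_ids) != m:
            raise ValidationError("individual_ids length does not match row count")
        else:
            object.__setattr__(self, "individual_ids", tuple(self.individual_ids))

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a tidy DataFrame with metadata columns first."""
        df = pd.DataFrame(self.values, columns=list(self.trait_names))
        df.insert(0, "margin_status", self.margin_status)
        df.insert(0, "population", self.population)
        df.insert(0, "species", self.species)
        df.insert(0, "individual_id", list(self.individual_ids))
        return df


@dataclass(frozen=True)
class CovarianceEstimate:
    """A symmetric PSD trait covariance (or correlation) matrix with context.

    ``n`` is the number of individuals the matrix was estimated from; the
    divisor used is ``n - 1`` (unbiased).  ``scale`` is ``"covariance"``
    (mm^2) or ``"correlation"`` (unit diagonal).
    """

    matrix: np.ndarray
    n: int
    trait_names: tuple[str, ...]
    scale: str = "covariance"
    species: str | None = None
    population: str | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        if self.scale not in ("covariance", "correlation"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        p = mat.shape[0]
        if mat.shape != (p, p) or len(self.trait_names) != p:
            raise ValidationError("matrix must be square and match trait_names")
        if not np.allclose(mat, mat.T, atol=1e-12, rtol=0):
            raise ValidationError("matrix is not symmetric to 1e-12")
        evals = np.linalg.eigvalsh(mat)
        if evals.min() < -1e-10 * max(1.0, evals.max()):
            raise ValidationError(
                f"matrix is not PSD (minimum eigenvalue {evals.min():.3e})"
            )
        if self.scale == "correlation" and not np.allclose(
            np.diag(mat), 1.0, atol=1e-10
        ):
            raise ValidationError("correlation matrix must have unit diagonal")

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[0]

    def to_correlation(self) -> "CovarianceEstimate":
        """Rescale to a correlation matrix (no-op if already on that scale)."""
        if self.scale == "correlation":
            return self
        d = np.sqrt(np.diag(self.matrix))
        corr = self.matrix / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        corr = (corr + corr.T) / 2.0
        return replace(self, matrix=corr, scale="correlation")


def read_trait_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
) -> TraitTable:
    """Read one population's trait table from a delimited text file.

    The file must have a header row and one row per individual, with the
    metadata columns ``individual_id, species, population, margin_status``
    followed by trait columns named by canonical code.  The delimiter
    (comma or tab) is sniffed from the header line.  ``schema`` optionally
    maps file column names to canonical ones.

    Raises
    ------
    ValidationError
        On missing cells, non-positive measurements, or unknown trait names.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if schema:
        df = df.rename(columns=schema)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValidationError(f"missing metadata column(s): {missing_meta}")
    trait_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in trait_cols if c not in CANONICAL_TRAITS]
    if unknown:
        raise ValidationError(
            f"unknown trait name(s) {unknown}; allowed: {list(CANONICAL_TRAITS)}"
        )
    for col in trait_cols:
        nulls = df.index[df[col].isna()]
        if len(nulls):
            raise ValidationError(
                f"missing value, row {nulls[0] + 1}, trait {col}"
            )
    species = _unique_label(df, "species")
    population = _unique_label(df, "population")
    margin = _unique_label(df, "margin_status")
    return TraitTable(
        species=species,
        population=population,
        margin_status=margin,
        trait_names=tuple(trait_cols),
        values=df[trait_cols].to_numpy(dtype=float),
        individual_ids=tuple(str(x) for x in df["individual_id"]),
    )


def write_trait_table(table: TraitTable, path: str | Path) -> Path:
    """Write a trait table as CSV; round-trips bit-exactly through pandas."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)
    return path


def _unique_label(df: pd.DataFrame, column: str) -> str:
    vals = df[column].unique()
    if len(vals) != 1:
        raise ValidationError(
            f"column {column!r} must be constant within one table, got {list(vals)}"
        )
    return str(vals[0])


def apply_trait_subset(table: TraitTable, genus: str | None = None) -> TraitTable:
    """Restrict a 9-trait table to the traits measurable for its genus.

    Amphiprion keeps all nine traits; Chrysiptera drops NPL and HDL (7 kept);
    Amblygobius drops HDL, EYD and PFD (6 kept).  ``genus`` defaults to the
    first word of ``table.species``.
    """
    if genus is None:
        genus = table.species.split()[0]
    if genus not in GENUS_TRAIT_DROPS:
        raise ValidationError(
            f"unknown genus {genus!r}; known: {sorted(GENUS_TRAIT_DROPS)}"
        )
    drops = GENUS_TRAIT_DROPS[genus]
    if not drops:
        return table
    keep = [i for i, t in enumerate(table.trait_names) if t not in drops]
    return replace(
        table,
        trait_names=tuple(table.trait_names[i] for i in keep),
        values=table.values[:, keep],
    )


def sample_covariance(
    table: TraitTable,
    scale: str = "covariance",
    log_transform: bool = False,
) -> CovarianceEstimate:
    """Unbiased sample covariance (divisor ``M - 1``) of one population.

    With ``scale="correlation"`` the matrix is standardised to unit diagonal.
    ``log_transform`` computes the covariance of natural-log traits instead
    of raw mm; the choice is recorded on the returned estimate.
    """
    if table.n_individuals < 2:
        raise ValidationError("need at least 2 individuals for a covariance")
    x = np.log(table.values) if log_transform else table.values
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    variances = np.diag(cov)
    if scale == "correlation":
        if np.any(variances <= 0):
            zero = table.trait_names[int(np.argmin(variances))]
            raise ValidationError(f"zero-variance trait {zero}: correlation undefined")
        d = np.sqrt(variances)
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
    elif scale != "covariance":
        raise ValidationError(f"unknown scale {scale!r}")
    cov = (cov + cov.T) / 2.0
    return CovarianceEstimate(
        matrix=cov,
        n=table.n_individuals,
        trait_names=table.trait_names,
        scale=scale,
        species=table.species,
        population=table.population,
        log_scale=log_transform,
    )


def write_covariance(est: CovarianceEstimate, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a covariance estimate as TSV (labelled matrix) or JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df = pd.DataFrame(
            est.matrix, index=list(est.trait_names), columns=list(est.trait_names)
        )
        df.to_csv(path, sep="\t", index_label="trait")
    elif fmt == "json":
        import json

        payload = {
            "species": est.species,
            "population": est.population,
            "n": est.n,
            "scale": est.scale,
            "log_scale": est.log_scale,
            "trait_names": list(est.trait_names),
            "matrix": est.matrix.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValidationError(f"unknown covariance output format {fmt!r}")
    return path
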