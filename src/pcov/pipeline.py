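"""End-to-end comparative analysis over a study design.

For every species the pipeline computes the phenotypic covariance matrix of
each of its two populations, fits the full Flury hierarchy with both
selectors, compares all pairwise trait correlations between sites with the
NIW posterior, and computes integration (relSD(lambda)) and measurement-
error rank per population.  The assembled report mirrors the result
surfaces of a central-vs-marginal covariance study: a hierarchy ladder per
congeneric pair, per-model confidence sets, an integration/rank table and
correlation-difference tables, plus the pooled share of trait pairs whose
correlation is stronger at the northern site.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, cpc, integration
from .datamodel import TraitTable, ValidationError, apply_trait_subset, sample_covariance
from .study import REFERENCE_STUDY, StudyDesign

logger = logging.getLogger("pcov")

__all__ = ["StudyReport", "run_study", "render_report"]


@dataclass(frozen=True)
class SpeciesResult:
    species: str
    is_focal: bool
    sites: tuple[str, str]
    hierarchy: cpc.HierarchyResult
    corr_diff: pd.DataFrame  # difference site_a - site_b (north - south)


@dataclass(frozen=True)
class StudyReport:
    design: StudyDesign
    species_results: tuple[SpeciesResult, ...]
    integration_table: pd.DataFrame
    north_share: dict
    config: dict

    def selected_levels(self) -> pd.DataFrame:
        rows = []
        for r in self.species_results:
            rows.append(
                {
                    "species": r.species,
                    "role": "focal" if r.is_focal else "control",
                    "stepup": str(r.hierarchy.stepup_selected),
                    "aic": str(r.hierarchy.aic_selected),
                    "confidence_set": ", ".join(
                        str(l) for l in r.hierarchy.confidence_set
                    ),
                }
            )
        return pd.DataFrame(rows)


def run_study(
    design: StudyDesign,
    tables: dict[tuple[str, str], TraitTable],
    alpha: float = 0.05,
    draws: int = 20_000,
    seed: int = 0,
    error_pct: float = 1.0,
    config: dict | None = None,
) -> StudyReport:
    """Run the full comparative analysis and assemble a StudyReport.

    ``tables`` maps (species, site) to a trait table; tables with all nine
    canonical traits are first restricted to their genus subset.  ``seed``
    drives the posterior sampling (one derived stream per species-site).
    """
    design.validate_tables(tables)
    prepared: dict[tuple[str, str], TraitTable] = {}
    for key, table in tables.items():
        if table.n_traits == 9:
            table = apply_trait_subset(table)
        prepared[key] = table

    species_results: list[SpeciesResult] = []
    corr_tables: dict[str, pd.DataFrame] = {}
    north, south = design.north_site, design.south_site
    seed_seq = np.random.SeedSequence(seed)
    sub_seeds = iter(seed_seq.generate_state(4 * len(design.species)))
    for sp in design.species:
        t_north = prepared[(sp.species, north)]
        t_south = prepared[(sp.species, south)]
        t0 = time.perf_counter()
        estimates = [sample_covariance(t) for t in (t_north, t_south)]
        try:
            hier = cpc.fit_hierarchy(estimates, alpha=alpha)
        except cpc.ConvergenceError as exc:
            raise cpc.ConvergenceError(
                f"hierarchy fit failed for {sp.species}: {exc}"
            ) from exc
        prior = bayes.default_prior(t_north, t_south)
        post_n = bayes.posterior_sample(
            t_north, prior, draws=draws, seed=int(next(sub_seeds)))
        post_s = bayes.posterior_sample(
            t_south, prior, draws=draws, seed=int(next(sub_seeds)))
        diff = bayes.correlation_difference(post_n, post_s)
        corr_tables[sp.species] = diff
        species_results.append(
            SpeciesResult(
                species=sp.species,
                is_focal=sp.is_focal,
                sites=(north, south),
                hierarchy=hier,
                corr_diff=diff,
            )
        )
        logger.info(
            "species=%s stage=hierarchy+posterior elapsed=%.1fs stepup=%s aic=%s",
            sp.species, time.perf_counter() - t0,
            hier.stepup_selected, hier.aic_selected,
        )

    populations = [prepared[(sp.species, site)]
                   for sp in design.species for site in (north, south)]
    integ = integration.build_integration_report(populations, error_pct=error_pct,
                                                 alpha=alpha)
    share = bayes.summarize_north_share(corr_tables, north_site=north)
    return StudyReport(
        design=design,
        species_results=tuple(species_results),
        integration_table=integ,
        north_share=share,
        config={
            "alpha": alpha, "draws": draws, "seed": seed,
            "error_pct": error_pct, **(config or {}),
        },
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _ladder_text(result: cpc.HierarchyResult, title: str) -> str:
    """Text figure of the hierarchy ladder with each selector's rung."""
    lines = [title, "-" * len(title)]
    header = f"{'level':>14} {'chi2':>10} {'df':>4} {'AIC':>10} {'weight':>7}  sel"
    lines.append(header)
    weights = dict(zip(result.levels, result.weights))
    for fit in reversed(result.fits):  # most constrained on top
        marks = []
        if fit.level == result.stepup_selected:
            marks.append("step-up")
        if fit.level == result.aic_selected:
            marks.append("AIC")
        star = "*" if fit.level in result.confidence_set else " "
        lines.append(
            f"{str(fit.level):>14} {fit.chi2:>10.2f} {fit.df_vs_unrelated:>4d} "
            f"{fit.aic:>10.2f} {weights[fit.level]:>7.3f} {star} {', '.join(marks)}"
        )
    return "\n".join(lines)


def _hierarchy_records(report: StudyReport) -> list[dict]:
    records = []
    for r in report.species_results:
        weights = dict(zip(r.hierarchy.levels, r.hierarchy.weights))
        for fit in r.hierarchy.fits:
            records.append(
                {
                    "species": r.species,
                    "role": "focal" if r.is_focal else "control",
                    "level": str(fit.level),
                    "chi2": fit.chi2,
                    "df": fit.df_vs_unrelated,
                    "params": fit.params,
                    "aic": fit.aic,
                    "weight": weights[fit.level],
                    "in_confidence_set": fit.level in r.hierarchy.confidence_set,
                    "stepup_selected": fit.level == r.hierarchy.stepup_selected,
                    "aic_selected": fit.level == r.hierarchy.aic_selected,
                }
            )
    return records


def render_report(
    report: StudyReport, outdir: str | Path, fmt: str = "tsv"
) -> list[Path]:
    """Write the report's tables in ``tsv``, ``json`` or ``markdown`` form.

    TSV output: hierarchy.tsv (per-model fits), selections.tsv,
    integration_rank.tsv and one correlation-difference table per species.
    JSON output: a single study_report.json.  Markdown: study_report.md
    with one hierarchy ladder per species.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    provenance = f"# pcov study report; config={json.dumps(report.config, sort_keys=True)}\n"

    if fmt == "tsv":
        def _write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(provenance)
                df.to_csv(fh, sep="\t", index=False)
            written.append(path)

        _write(pd.DataFrame(_hierarchy_records(report)), "hierarchy.tsv")
        _write(report.selected_levels(), "selections.tsv")
        _write(report.integration_table, "integration_rank.tsv")
        for r in report.species_results:
            slug = r.species.replace(" ", "_")
            _write(r.corr_diff, f"corr_diff_{slug}.tsv")
    elif fmt == "json":
        payload = {
            "config": report.config,
            "north_share": report.north_share,
            "hierarchy": _hierarchy_records(report),
            "selections": report.selected_levels().to_dict(orient="records"),
            "integration_rank": report.integration_table.to_dict(orient="records"),
            "corr_diff": {
                r.species: r.corr_diff.to_dict(orient="records")
                for r in report.species_results
            },
        }
        path = outdir / "study_report.json"
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(path)
    elif fmt == "markdown":
        parts = ["# Study report", ""]
        for r in report.species_results:
            role = "focal" if r.is_focal else "control"
            parts.append("```")
            parts.append(_ladder_text(r.hierarchy, f"{r.species} ({role})"))
            parts.append("```")
            parts.append("")
        parts.append("## Integration and rank")
        parts.append(report.integration_table.to_markdown(index=False))
        parts.append("")
        share = report.north_share
        parts.append(
            f"Trait-pair correlations stronger at {share['north_site']}: "
            f"{share['north_stronger']}/{share['pairs']} "
            f"({100 * share['proportion_north_stronger']:.0f}%)."
        )
        path = outdir / "study_report.md"
        path.write_text("\n".join(parts))
        written.append(path)
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
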