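"""End-to-end orchestration and report generation.

Fixed stage order: translate (both routes) -> common list -> volatility
-> classification/profiles -> pathway enrichment -> conservative filter
-> report.  Every stage is deterministic; rerunning on the same inputs
yields an identical report.  Intermediate tables are written as TSV and
the report as JSON when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_STUDIES,
    conservative_filter,
    enriched_pathways,
    pathway_enrichment,
)
from .profiles import compare_profiles, genome_volatilome, study_volatilome
from .translate import (
    common_compound_table,
    common_enzymes,
    compound_study_table,
    translate_ko_style,
    translate_swissprot_style,
)
from .universe import STUDY_LABELS, Universe, load_universe
from .volatility import DEFAULT_TEMPERATURE, assess_universe, load_coefficients

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    temperature: float = DEFAULT_TEMPERATURE
    alpha: float = DEFAULT_ALPHA
    min_studies: int = DEFAULT_MIN_STUDIES
    substrates_only: bool = False
    profile_level: str = "subclass"
    per_domain_means: bool = False
    coefficients_path: str | None = None


@dataclass
class RunReport:
    method_counts: dict[str, dict[str, int]]
    per_study_volatile_counts: dict[str, dict[str, int]]
    overlap: dict[str, dict[str, float]]
    n_common_enzymes: int
    n_common_compounds: int
    funnel: dict[str, int]
    enrichment: list[dict]
    enriched_pathways: list[str]
    final_vocs: list[dict]
    profile_comparison: list[dict]
    config: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def overlap_statistics(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per method: percent of compounds supported by >= 2 studies, and the
    count supported by exactly one."""
    if table.empty:
        raise ValueError("empty compound-study table")
    out: dict[str, dict[str, float]] = {}
    for method, sub in table.groupby("method"):
        n = len(sub)
        multi = int((sub["n_studies"] >= 2).sum())
        single = int((sub["n_studies"] == 1).sum())
        out[method] = {
            "percent_multi_study": 100.0 * multi / n,
            "n_single_study": single,
            "n_compounds": n,
        }
    return out


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_all(
    universe: Universe | str | Path,
    config: PipelineConfig | None = None,
    cog_set: set[str] | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the full pipeline over a universe (object or directory).

    ``cog_set`` defaults to every ortholog group in the universe (the
    whole table is the ancestral COG collection).
    """
    config = config or PipelineConfig()
    if not isinstance(universe, Universe):
        universe = _stage("load")(load_universe)(universe)
    if cog_set is None:
        cog_set = set(universe.cogs)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- translate -------------------------------------------------------
    r1 = _stage("translate")(translate_swissprot_style)(cog_set, universe)
    r2 = _stage("translate")(translate_ko_style)(cog_set, universe)
    common = _stage("common_list")(common_enzymes)(
        r1, r2, universe, substrates_only=config.substrates_only
    )

    # -- volatility ------------------------------------------------------
    coeffs = load_coefficients(config.coefficients_path)
    volatility = _stage("volatility")(assess_universe)(
        universe, coeffs, config.temperature
    )

    def n_volatile(compound_ids) -> int:
        return sum(
            1 for c in compound_ids
            if volatility[c].assessable and volatility[c].category == "high"
        )

    tables = {}
    method_counts = {}
    for result in (r1, r2):
        table = compound_study_table(
            result, universe, substrates_only=config.substrates_only
        )
        volatile_mask = table["compound_id"].map(
            lambda c: volatility[c].assessable and volatility[c].category == "high"
        )
        tables[result.method] = table[volatile_mask].reset_index(drop=True)
        method_counts[result.method] = {
            "n_enzymes": len(result.accepted_ecs),
            "n_compounds": int(len(table)),
            "n_volatile": int(volatile_mask.sum()),
        }

    common_table = common_compound_table(
        common, universe, substrates_only=config.substrates_only
    )
    common_volatile = common_table[
        common_table["compound_id"].map(
            lambda c: volatility[c].assessable and volatility[c].category == "high"
        )
    ].reset_index(drop=True)

    overlap = _stage("overlap")(overlap_statistics)(
        pd.concat(list(tables.values()), ignore_index=True)
    ) if any(len(t) for t in tables.values()) else {}

    per_study = {}
    for study in sorted(STUDY_LABELS):
        per_study[study] = {
            method: int(
                table["studies"].str.split(";").map(lambda s: study in s).sum()
            )
            for method, table in tables.items()
        }

    # -- profiles --------------------------------------------------------
    study_profiles = [
        study_volatilome(study, common_volatile, universe, volatility,
                         config.profile_level)
        for study in sorted(STUDY_LABELS)
    ]
    genome_profiles = [
        genome_volatilome(g, universe, volatility, config.profile_level)
        for _, g in sorted(universe.genomes.items())
    ]
    nonempty_s = [p for p in study_profiles if not p.empty]
    nonempty_g = [p for p in genome_profiles if not p.empty]
    if len(nonempty_s) >= 2 and len(nonempty_g) >= 2:
        domains = {g.genome_id: g.domain for g in universe.genomes.values()}
        comparison = _stage("profiles")(compare_profiles)(
            nonempty_s, nonempty_g,
            per_domain_means=config.per_domain_means, domains=domains,
        )
    else:
        logger.warning("too few non-empty profiles for a class comparison")
        comparison = pd.DataFrame(
            columns=["subclass", "luca_mean", "modern_mean", "p_value"]
        )

    # -- enrichment and filter -------------------------------------------
    enrichment = _stage("enrichment")(pathway_enrichment)(
        common.ec_set, universe, config.alpha
    )
    traces, final, funnel = _stage("filter")(conservative_filter)(
        common, volatility, enrichment, universe,
        alpha=config.alpha, min_studies=config.min_studies,
        substrates_only=config.substrates_only,
    )

    study_support = {
        row.compound_id: row.studies
        for row in common_table.itertuples(index=False)
    }
    final_vocs = [
        {
            "compound_id": cid,
            "name": universe.compounds[cid].name,
            "superclass": universe.chem_taxonomy[cid].superclass
            if cid in universe.chem_taxonomy else "unclassified",
            "studies": study_support.get(cid, ""),
        }
        for cid in final
    ]

    report = RunReport(
        method_counts=method_counts,
        per_study_volatile_counts=per_study,
        overlap=overlap,
        n_common_enzymes=len(common.ecs),
        n_common_compounds=len(common.compounds),
        funnel=funnel,
        enrichment=[
            {
                "pathway_id": r.pathway_id,
                "n_universe": r.n_universe,
                "n_luca": r.n_luca,
                "n_pathway": r.n_pathway,
                "n_overlap": r.n_overlap,
                "p_value": r.p_value,
                "enzyme_coverage": r.enzyme_coverage,
            }
            for r in enrichment
        ],
        enriched_pathways=sorted(enriched_pathways(enrichment, config.alpha)),
        final_vocs=final_vocs,
        profile_comparison=comparison.to_dict(orient="records"),
        config=dataclasses.asdict(config),
    )

    if out is not None:
        for method, table in tables.items():
            table.to_csv(out / f"volatiles_{method}.tsv", sep="\t", index=False)
        common_volatile.to_csv(out / "volatiles_common.tsv", sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(t) for t in traces]
        ).to_csv(out / "filter_traces.tsv", sep="\t", index=False)
        pd.DataFrame(report.enrichment).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        comparison.to_csv(out / "profile_comparison.tsv", sep="\t", index=False)
        pd.DataFrame(final_vocs).to_csv(out / "final_vocs.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")

    return report
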