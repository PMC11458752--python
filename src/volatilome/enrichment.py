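"""Pathway enrichment and the conservative ancestral-VOC filter.

Enrichment asks, per pathway, whether it contains more ancestral
enzymes than expected if the ancestral set were drawn at random from
all enzymes: the upper-tail hypergeometric probability
P(X >= n_overlap) for X ~ Hypergeom(n_universe, n_luca, n_pathway),
computed in log space.

The conservative filter then keeps a compound only if it

1. is on the common list (accepted by both translation routes),
2. is organic,
3. is classed high-volatility,
4. has confirmed emissions from modern organisms,
5. is a substrate of an ancestral enzyme through a reaction that lies
   inside an enriched pathway containing that enzyme, and
6. is supported by at least ``min_studies`` of the eight source studies.

Every candidate gets a full :class:`FilterTrace`; nothing is silently
dropped, and the stage-by-stage funnel counts are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from rdkit import Chem
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .translate import CommonList
from .universe import CompoundRecord, Universe
from .volatility import VolatilityResult

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_STUDIES = 4

# Carbon-containing species conventionally treated as inorganic
# (canonical SMILES): CO2, CO, carbonic acid, bicarbonate, carbonate,
# hydrogen cyanide / cyanide.
_INORGANIC_CARBON_SMILES = {
    Chem.CanonSmiles(s)
    for s in ["O=C=O", "[C-]#[O+]", "OC(=O)O", "OC(=O)[O-]",
              "[O-]C(=O)[O-]", "C#N", "[C-]#N"]
}


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    n_universe: int
    n_luca: int
    n_pathway: int
    n_overlap: int
    p_value: float

    @property
    def enzyme_coverage(self) -> float:
        return self.n_overlap / self.n_pathway if self.n_pathway else 0.0


@dataclass(frozen=True)
class FilterTrace:
    compound_id: str
    in_common_list: bool
    is_organic: bool
    is_high_volatility: bool
    emission_confirmed: bool
    in_enriched_pathway_with_luca_enzyme: bool
    study_support_count: int
    final: bool

    def flags(self) -> tuple[bool, ...]:
        return (
            self.in_common_list,
            self.is_organic,
            self.is_high_volatility,
            self.emission_confirmed,
            self.in_enriched_pathway_with_luca_enzyme,
        )


def hypergeom_upper_tail(
    n_universe: int, n_luca: int, n_pathway: int, n_overlap: int
) -> float:
    """P(X >= n_overlap), X ~ Hypergeom(n_universe, n_luca, n_pathway),
    accumulated in log space for numerical stability."""
    if n_overlap <= 0:
        return 1.0
    lo = max(0, n_luca + n_pathway - n_universe)
    hi = min(n_luca, n_pathway)
    if n_overlap > hi:
        return 0.0
    logs = [
        hypergeom.logpmf(k, n_universe, n_luca, n_pathway)
        for k in range(max(n_overlap, lo), hi + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(logs))))


def pathway_enrichment(
    luca_ecs: set[str],
    universe: Universe,
    alpha: float = DEFAULT_ALPHA,
    pathway_members_only: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of ancestral enzymes in each pathway.

    The sampling universe is every enzyme in the enzyme table by default;
    ``pathway_members_only`` restricts it to enzymes that belong to at
    least one pathway.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    unknown = luca_ecs - universe.enzymes.keys()
    if unknown:
        raise KeyError(f"ancestral ECs not in universe: {sorted(unknown)}")

    if pathway_members_only:
        pool = {ec for ec, e in universe.enzymes.items() if e.pathway_ids}
    else:
        pool = set(universe.enzymes)
    luca_in_pool = luca_ecs & pool
    results = []
    for pid, pathway in sorted(universe.pathways.items()):
        members = pathway.ec_numbers & pool
        if not members:
            logger.warning("pathway %s has no enzymes in the pool; skipped", pid)
            continue
        overlap = members & luca_in_pool
        p = hypergeom_upper_tail(len(pool), len(luca_in_pool), len(members), len(overlap))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                n_universe=len(pool),
                n_luca=len(luca_in_pool),
                n_pathway=len(members),
                n_overlap=len(overlap),
                p_value=p,
            )
        )
    return results


def enriched_pathways(results: list[EnrichmentResult], alpha: float = DEFAULT_ALPHA) -> set[str]:
    return {r.pathway_id for r in results if r.p_value < alpha}


def voc_pathway_support(
    voc: str,
    luca_ecs: set[str],
    enriched: set[str],
    universe: Universe,
    substrates_only: bool = False,
) -> tuple[bool, list[tuple[str, str]]]:
    """Does an enriched pathway contain an ancestral enzyme whose linking
    reaction (the one associating it with ``voc``) lies in that pathway's
    reaction scope?  Returns the flag and the supporting (ec, pathway)
    pairs."""
    support: list[tuple[str, str]] = []
    for ec in sorted(luca_ecs):
        enzyme = universe.enzymes.get(ec)
        if enzyme is None:
            continue
        # reactions of this enzyme that associate it with the voc
        linking = set()
        for rid in enzyme.reaction_ids:
            rxn = universe.reactions[rid]
            assoc = set(rxn.substrate_ids)
            if rxn.reversible and not substrates_only:
                assoc |= rxn.product_ids
            if voc in assoc:
                linking.add(rid)
        if not linking:
            continue
        for pid in sorted(enzyme.pathway_ids & enriched):
            if linking & universe.pathway_reaction_scope(pid):
                support.append((ec, pid))
    return bool(support), support


def _carbon_count_from_formula(formula: str) -> int:
    import re

    count = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if m.group(1) == "C":
            count += int(m.group(2) or 1)
    return count


def is_organic(compound: CompoundRecord) -> bool:
    """Organic = contains carbon, excluding conventional inorganic-carbon
    species (CO2, CO, carbonate/bicarbonate, cyanide)."""
    if compound.smiles:
        mol = Chem.MolFromSmiles(compound.smiles)
        if mol is None:
            raise ValueError(f"{compound.compound_id}: unparseable SMILES")
        n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
        if n_carbon == 0:
            return False
        return Chem.CanonSmiles(compound.smiles) not in _INORGANIC_CARBON_SMILES
    if compound.formula:
        return _carbon_count_from_formula(compound.formula) > 0
    raise ValueError(f"{compound.compound_id}: no structure and no formula")


def emission_confirmed(compound_id: str, universe: Universe) -> bool:
    record = universe.emissions.get(compound_id)
    return bool(record and record.confirmed)


def conservative_filter(
    common: CommonList,
    volatility_results: dict[str, VolatilityResult],
    enrichment: list[EnrichmentResult],
    universe: Universe,
    alpha: float = DEFAULT_ALPHA,
    min_studies: int = DEFAULT_MIN_STUDIES,
    substrates_only: bool = False,
) -> tuple[list[FilterTrace], list[str], dict[str, int]]:
    """Apply the conservative multi-criteria filter to the common list.

    Returns ``(traces, final_voc_ids, funnel)`` where ``funnel`` gives the
    surviving count after each successive stage.
    """
    enriched = enriched_pathways(enrichment, alpha)
    luca_ecs = common.ec_set

    traces: list[FilterTrace] = []
    for cid in sorted(common.compounds):
        compound = universe.compounds.get(cid)
        if compound is None:
            raise KeyError(f"common-list compound {cid} not in universe")
        vres = volatility_results.get(cid)
        if vres is None:
            raise ValueError(f"missing volatility result for common-list compound {cid}")
        organic = is_organic(compound)
        high = bool(vres.assessable and vres.category == "high")
        emitted = emission_confirmed(cid, universe)
        supported, _pairs = voc_pathway_support(
            cid, luca_ecs, enriched, universe, substrates_only=substrates_only
        )
        studies: set[str] = set()
        for ec in luca_ecs:
            if cid in universe.compounds_for_enzyme(ec, substrates_only=substrates_only):
                studies |= common.ecs[ec].source_studies
        trace = FilterTrace(
            compound_id=cid,
            in_common_list=True,
            is_organic=organic,
            is_high_volatility=high,
            emission_confirmed=emitted,
            in_enriched_pathway_with_luca_enzyme=supported,
            study_support_count=len(studies),
            final=(
                organic
                and high
                and emitted
                and supported
                and len(studies) >= min_studies
            ),
        )
        traces.append(trace)

    funnel = funnel_counts(traces, min_studies)
    final = [t.compound_id for t in traces if t.final]
    logger.info("conservative filter funnel: %s", funnel)
    return traces, final, funnel


def funnel_counts(traces: list[FilterTrace], min_studies: int = DEFAULT_MIN_STUDIES) -> dict[str, int]:
    """Stage-by-stage survivor counts (each stage conjoined with all
    previous ones, in filter order)."""
    stages = {
        "common": lambda t: t.in_common_list,
        "organic": lambda t: t.is_organic,
        "high_volatility": lambda t: t.is_high_volatility,
        "emission_confirmed": lambda t: t.emission_confirmed,
        "enriched_supported": lambda t: t.in_enriched_pathway_with_luca_enzyme,
        "final": lambda t: t.study_support_count >= min_studies,
    }
    out: dict[str, int] = {}
    survivors = list(traces)
    for name, pred in stages.items():
        survivors = [t for t in survivors if pred(t)]
        out[name] = len(survivors)
    return out
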