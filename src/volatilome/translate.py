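"""Ortholog-group to enzyme translation under taxonomic-distribution criteria.

Two independent routes mirror curated-protein versus ortholog-database
translation of an ancestral COG set:

* ``translate_swissprot_style`` — an EC number is accepted when some COG
  in the input links to protein records carrying it AND, across all
  protein records carrying that EC, all three domains of life (Bacteria,
  Archaea, Eukaryota) are represented.

* ``translate_ko_style`` — a KO is accepted when linked to an input COG
  AND the genomes containing it span at least two distinct phyla in each
  of Bacteria and Archaea; accepted ECs are the union over accepted KOs.

``common_enzymes`` intersects the two results ("common list") and pulls
in the associated compounds; study provenance is propagated throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .universe import Universe

logger = logging.getLogger(__name__)

SWISSPROT_STYLE = "swissprot_style"
KO_STYLE = "ko_style"


@dataclass(frozen=True)
class Provenance:
    source_cogs: frozenset[str]
    source_studies: frozenset[str]


@dataclass(frozen=True)
class TranslationResult:
    method: str
    accepted_ecs: dict[str, Provenance]

    @property
    def ecs(self) -> set[str]:
        return set(self.accepted_ecs)


@dataclass(frozen=True)
class CommonList:
    ecs: dict[str, Provenance]
    compounds: set[str]

    @property
    def ec_set(self) -> set[str]:
        return set(self.ecs)


def _provenance_for_cogs(universe: Universe, cog_ids: set[str]) -> Provenance:
    studies: set[str] = set()
    for cid in cog_ids:
        studies |= universe.cogs[cid].source_studies
    return Provenance(frozenset(cog_ids), frozenset(studies))


def translate_swissprot_style(
    cog_set: set[str],
    universe: Universe,
    per_cog_domains: bool = False,
) -> TranslationResult:
    """Curated-protein route with the three-domain span criterion.

    By default the domain span of an EC is evaluated over *all* protein
    records carrying it, mirroring a database-wide distribution check;
    ``per_cog_domains`` restricts the check to proteins linked from the
    contributing COGs.
    """
    unknown = cog_set - universe.cogs.keys()
    if unknown:
        raise KeyError(f"unknown COGs: {sorted(unknown)}")
    if not cog_set:
        logger.warning("empty COG set: empty translation result")
        return TranslationResult(SWISSPROT_STYLE, {})

    # EC -> COGs that link to a protein carrying it
    ec_cogs: dict[str, set[str]] = {}
    ec_cog_domains: dict[str, set[str]] = {}
    for cid in cog_set:
        for pid in universe.cogs[cid].linked_protein_ids:
            prot = universe.proteins[pid]
            for ec in prot.ec_numbers:
                ec_cogs.setdefault(ec, set()).add(cid)
                ec_cog_domains.setdefault(ec, set()).add(prot.domain)

    # EC -> domains across the whole protein table
    ec_domains_global: dict[str, set[str]] = {}
    for prot in universe.proteins.values():
        for ec in prot.ec_numbers:
            ec_domains_global.setdefault(ec, set()).add(prot.domain)

    accepted: dict[str, Provenance] = {}
    for ec, cogs in ec_cogs.items():
        domains = ec_cog_domains[ec] if per_cog_domains else ec_domains_global[ec]
        if domains >= {"Bacteria", "Archaea", "Eukaryota"}:
            accepted[ec] = _provenance_for_cogs(universe, cogs)
    logger.info("swissprot-style: %d COGs -> %d accepted ECs", len(cog_set), len(accepted))
    return TranslationResult(SWISSPROT_STYLE, accepted)


def translate_ko_style(
    cog_set: set[str],
    universe: Universe,
    min_phyla: int = 2,
) -> TranslationResult:
    """Ortholog-database route with the two-phyla-per-prokaryotic-domain
    criterion (``min_phyla`` distinct phyla in each of Bacteria and
    Archaea; eukaryotes are ignored by the criterion)."""
    unknown = cog_set - universe.cogs.keys()
    if unknown:
        raise KeyError(f"unknown COGs: {sorted(unknown)}")
    if not cog_set:
        logger.warning("empty COG set: empty translation result")
        return TranslationResult(KO_STYLE, {})
    for g in universe.genomes.values():
        if not g.phylum:
            raise ValueError(f"genome {g.genome_id} lacks a phylum label")

    # KO -> phyla per prokaryotic domain
    ko_phyla: dict[str, dict[str, set[str]]] = {}
    for g in universe.genomes.values():
        if g.domain not in ("Bacteria", "Archaea"):
            continue
        for ko in g.ko_ids:
            ko_phyla.setdefault(ko, {"Bacteria": set(), "Archaea": set()})[
                g.domain
            ].add(g.phylum)

    accepted: dict[str, Provenance] = {}
    for ko in universe.kos.values():
        cogs = set(ko.linked_cog_ids) & cog_set
        if not cogs:
            continue
        phyla = ko_phyla.get(ko.ko_id, {"Bacteria": set(), "Archaea": set()})
        if len(phyla["Bacteria"]) < min_phyla or len(phyla["Archaea"]) < min_phyla:
            continue
        for ec in ko.ec_numbers:
            prev = accepted.get(ec)
            merged = cogs | (set(prev.source_cogs) if prev else set())
            accepted[ec] = _provenance_for_cogs(universe, merged)
    logger.info("ko-style: %d COGs -> %d accepted ECs", len(cog_set), len(accepted))
    return TranslationResult(KO_STYLE, accepted)


def common_enzymes(
    r1: TranslationResult,
    r2: TranslationResult,
    universe: Universe,
    substrates_only: bool = False,
) -> CommonList:
    """Intersection of the two translation routes, with merged provenance
    and the union of associated compounds."""
    if r1.method == r2.method:
        raise ValueError("common_enzymes requires results from two distinct methods")
    shared = r1.ecs & r2.ecs
    if not shared:
        logger.warning("translation methods share no enzymes")
    ecs: dict[str, Provenance] = {}
    for ec in shared:
        p1, p2 = r1.accepted_ecs[ec], r2.accepted_ecs[ec]
        ecs[ec] = Provenance(
            p1.source_cogs | p2.source_cogs,
            p1.source_studies | p2.source_studies,
        )
    compounds: set[str] = set()
    for ec in shared:
        compounds |= universe.compounds_for_enzyme(ec, substrates_only=substrates_only)
    logger.info("common list: %d ECs, %d compounds", len(ecs), len(compounds))
    return CommonList(ecs=ecs, compounds=compounds)


def compound_study_table(
    result: TranslationResult,
    universe: Universe,
    substrates_only: bool = False,
) -> pd.DataFrame:
    """One row per compound x method: the studies and ECs linking it.

    Study sets are unions over all accepted ECs associated with the
    compound; the table feeds the multi-study overlap statistics.
    """
    rows = []
    compound_ecs: dict[str, set[str]] = {}
    for ec in result.accepted_ecs:
        for cid in universe.compounds_for_enzyme(ec, substrates_only=substrates_only):
            compound_ecs.setdefault(cid, set()).add(ec)
    for cid in sorted(compound_ecs):
        studies: set[str] = set()
        for ec in compound_ecs[cid]:
            studies |= result.accepted_ecs[ec].source_studies
        rows.append(
            {
                "compound_id": cid,
                "method": result.method,
                "studies": ";".join(sorted(studies)),
                "n_studies": len(studies),
                "ecs": ";".join(sorted(compound_ecs[cid])),
            }
        )
    return pd.DataFrame(
        rows, columns=["compound_id", "method", "studies", "n_studies", "ecs"]
    )


def common_compound_table(
    common: CommonList,
    universe: Universe,
    substrates_only: bool = False,
) -> pd.DataFrame:
    """Compound x provenance table for the common list (method = 'common')."""
    as_result = TranslationResult("common", dict(common.ecs))
    return compound_study_table(as_result, universe, substrates_only=substrates_only)
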