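"""Synthetic knowledge universes with planted ancestral ground truth.

The generator emits a fully relational universe (ortholog groups,
proteins, KOs, genomes, enzymes, reactions, compounds, pathways,
emissions, chemical taxonomy) in which:

* planted ancestral enzymes are carried by proteins spanning all three
  domains of life AND by KOs spanning at least two phyla in each
  prokaryotic domain (degradable with ``distribution_noise``), so both
  translation routes accept them;
* planted enzymes are concentrated in designated "enriched" pathways;
* planted true VOCs are small, genuinely high-volatility molecules from
  a template library with hand-certified functional-group counts, are
  emission-confirmed, organic, and supported by at least four of the
  eight source studies;
* every true VOC is linked through *two* independently planted enzymes
  (each with its own KO), so that per-KO distribution noise ``p`` only
  removes a VOC with probability about ``p**2``;
* decoy compounds each violate exactly one conservative-filter
  criterion, so every filter stage is falsifiable in isolation.

All randomness flows from a single seeded generator; the same seed
yields byte-identical files on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from . import universe as U
from .universe import Universe
from .volatility import GroupCounts

STUDIES = ("Delaye", "Harris", "Mirkin", "Ranea", "Srinivasan", "Wang", "Weiss", "Yang")


class ConfigError(ValueError):
    pass


# ---- template molecule library -----------------------------------------


@dataclass(frozen=True)
class TemplateMolecule:
    name: str
    smiles: str
    certified_counts: dict[str, int]


def _t(name: str, smiles: str, **counts: int) -> TemplateMolecule:
    return TemplateMolecule(name, smiles, counts)


_TEMPLATES: tuple[TemplateMolecule, ...] = (
    # named early-metabolism compounds
    _t("methanol", "CO", carbon=1, hydroxyl=1),
    _t("ethanol", "CCO", carbon=2, hydroxyl=1),
    _t("formic acid", "OC=O", carbon=1, carboxylic_acid=1),
    _t("acetic acid", "CC(O)=O", carbon=2, carboxylic_acid=1),
    _t("acetaldehyde", "CC=O", carbon=2, aldehyde=1),
    _t("acetone", "CC(C)=O", carbon=3, ketone=1),
    _t("succinic acid", "OC(=O)CCC(O)=O", carbon=4, carboxylic_acid=2),
    _t("phenylpyruvate", "O=C(C(O)=O)Cc1ccccc1",
       carbon=9, aromatic_ring=1, carboxylic_acid=1, ketone=1),
    _t("putrescine", "NCCCCN", carbon=4, amine_primary=2),
    _t("octanoic acid", "CCCCCCCC(O)=O", carbon=8, carboxylic_acid=1),
    _t("4-aminobutanoic acid", "NCCCC(O)=O",
       carbon=4, carboxylic_acid=1, amine_primary=1),
    # further certified structures exercising every group kind
    _t("1-propanol", "CCCO", carbon=3, hydroxyl=1),
    _t("2-propanol", "CC(O)C", carbon=3, hydroxyl=1),
    _t("1-butanol", "CCCCO", carbon=4, hydroxyl=1),
    _t("ethylene glycol", "OCCO", carbon=2, hydroxyl=2),
    _t("glycerol", "OCC(O)CO", carbon=3, hydroxyl=3),
    _t("glucose", "OCC1OC(O)C(O)C(O)C1O", carbon=6, hydroxyl=5, ether=1),
    _t("propanoic acid", "CCC(O)=O", carbon=3, carboxylic_acid=1),
    _t("benzoic acid", "OC(=O)c1ccccc1",
       carbon=7, aromatic_ring=1, carboxylic_acid=1),
    _t("pyruvic acid", "CC(=O)C(O)=O", carbon=3, carboxylic_acid=1, ketone=1),
    _t("lactic acid", "CC(O)C(O)=O", carbon=3, carboxylic_acid=1, hydroxyl=1),
    _t("formaldehyde", "C=O", carbon=1, aldehyde=1),
    _t("propanal", "CCC=O", carbon=3, aldehyde=1),
    _t("benzaldehyde", "O=Cc1ccccc1", carbon=7, aromatic_ring=1, aldehyde=1),
    _t("butanone", "CCC(C)=O", carbon=4, ketone=1),
    _t("ethyl acetate", "CCOC(C)=O", carbon=4, ester=1),
    _t("methyl formate", "COC=O", carbon=2, ester=1),
    _t("methyl acetate", "COC(C)=O", carbon=3, ester=1),
    _t("diethyl ether", "CCOCC", carbon=4, ether=1),
    _t("anisole", "COc1ccccc1", carbon=7, aromatic_ring=1, ether=1),
    _t("phenol", "Oc1ccccc1", carbon=6, aromatic_ring=1, phenol=1),
    _t("nitromethane", "C[N+](=O)[O-]", carbon=1, nitro=1),
    _t("methylamine", "CN", carbon=1, amine_primary=1),
    _t("aniline", "Nc1ccccc1", carbon=6, aromatic_ring=1, amine_primary=1),
    _t("dimethylamine", "CNC", carbon=2, amine_secondary=1),
    _t("trimethylamine", "CN(C)C", carbon=3, amine_tertiary=1),
    _t("acetamide", "CC(N)=O", carbon=2, amide=1),
    _t("benzene", "c1ccccc1", carbon=6, aromatic_ring=1),
    _t("toluene", "Cc1ccccc1", carbon=7, aromatic_ring=1),
    _t("styrene", "C=Cc1ccccc1", carbon=8, aromatic_ring=1, carbon_double_bond=1),
    _t("isoprene", "C=C(C)C=C", carbon=5, carbon_double_bond=2),
    _t("methanethiol", "CS", carbon=1, unmatched_heteroatom=1),
    _t("methaneselenol", "C[SeH]", carbon=1, unmatched_heteroatom=1),
    _t("dimethyl sulfide", "CSC", carbon=2, unmatched_heteroatom=1),
    _t("icosan-icosaol", "OC" + "C(O)" * 18 + "CO", carbon=20, hydroxyl=20),
    _t("water", "O", unmatched_heteroatom=1),
    _t("ammonia", "N", unmatched_heteroatom=1),
    _t("carbon dioxide", "O=C=O", carbon=1, unmatched_heteroatom=2),
    _t("hydrogen cyanide", "C#N", carbon=1, unmatched_heteroatom=1),
)

#: Compounds whose structures carry the named-compound certification.
NAMED_COMPOUNDS = (
    "ethanol", "acetic acid", "formic acid", "acetaldehyde", "succinic acid",
    "phenylpyruvate", "methanol", "acetone", "putrescine", "octanoic acid",
    "4-aminobutanoic acid",
)


def template_molecules() -> dict[str, TemplateMolecule]:
    """SMILES library with hand-certified functional-group counts, used as
    the independent oracle for the group counter."""
    return {t.name: t for t in _TEMPLATES}


def certified_group_counts(t: TemplateMolecule) -> GroupCounts:
    from .volatility import GROUP_KINDS

    counts = {k: 0 for k in GROUP_KINDS}
    counts.update(t.certified_counts)
    return GroupCounts(counts=counts)


# ---- generator config ---------------------------------------------------


@dataclass(frozen=True)
class PlantedConfig:
    n_luca_ecs: int = 40
    n_enriched_pathways: int = 3
    n_true_vocs: int = 12
    background_link_density: float = 0.03
    distribution_noise: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_genomes_per_domain: dict[str, int] = field(
        default_factory=lambda: {"Bacteria": 30, "Archaea": 20, "Eukaryota": 10}
    )
    n_phyla_per_domain: dict[str, int] = field(
        default_factory=lambda: {"Bacteria": 6, "Archaea": 5, "Eukaryota": 4}
    )
    n_cogs: int = 120
    n_kos: int = 160
    n_ecs: int = 300
    n_reactions: int = 360
    n_compounds: int = 250
    n_pathways: int = 20
    planted: PlantedConfig = field(default_factory=PlantedConfig)

    def validate(self) -> None:
        p = self.planted
        if not 0 <= p.background_link_density <= 1:
            raise ConfigError("background_link_density must be in [0, 1]")
        if not 0 <= p.distribution_noise <= 1:
            raise ConfigError("distribution_noise must be in [0, 1]")
        if p.n_enriched_pathways > self.n_pathways:
            raise ConfigError("more enriched pathways than pathways")
        n_voc_candidates = len(_TRUE_VOC_CANDIDATES)
        if p.n_true_vocs > n_voc_candidates:
            raise ConfigError(f"at most {n_voc_candidates} true VOCs supported")
        if 2 * p.n_true_vocs > p.n_luca_ecs:
            raise ConfigError("need at least two planted enzymes per true VOC")
        n_planted_ecs = p.n_luca_ecs + len(_DECOY_EC_KINDS)
        if n_planted_ecs > self.n_ecs:
            raise ConfigError("planted enzymes exceed n_ecs")
        if n_planted_ecs + 4 > self.n_kos:
            raise ConfigError("planted KOs exceed n_kos")
        if len(_TEMPLATES) + 5 > self.n_compounds:
            raise ConfigError("n_compounds too small for template library")
        for dom in ("Bacteria", "Archaea"):
            if self.n_phyla_per_domain[dom] < 2:
                raise ConfigError("need >= 2 phyla in each prokaryotic domain")
            if self.n_genomes_per_domain[dom] < self.n_phyla_per_domain[dom]:
                raise ConfigError("need at least one genome per phylum")


# true-VOC candidates: organic, high-volatility templates (in plant order)
_TRUE_VOC_CANDIDATES = (
    "ethanol", "acetic acid", "formic acid", "acetaldehyde", "methanol",
    "acetone", "succinic acid", "phenylpyruvate", "1-propanol", "butanone",
    "formaldehyde", "methylamine",
)

# decoy compounds: each violates exactly one conservative-filter criterion
_DECOY_COMPOUNDS = {
    "inorganic": "carbon dioxide",        # fails is_organic only
    "low_volatility": "glucose",          # fails the high-volatility class only
    "no_emission": "diethyl ether",       # absent from the emission table only
    "non_enriched_pathway": "putrescine", # ancestral link sits outside enriched pathways
    "few_studies": "octanoic acid",       # < 4 supporting studies only
    "method1_only": "lactic acid",        # its enzyme fails the KO-route criterion
    "method2_only": "4-aminobutanoic acid",  # its enzyme fails the protein-route criterion
}

# extra planted enzymes that fail one translation route each
_DECOY_EC_KINDS = ("fails_domain_span", "fails_phyla_span", "eukaryote_only_ko")


@dataclass(frozen=True)
class TruthSet:
    luca_cogs: tuple[str, ...]
    luca_ecs: tuple[str, ...]
    enriched_pathways: tuple[str, ...]
    true_vocs: dict[str, tuple[str, ...]]  # compound_id -> study labels
    decoys: dict[str, str]                 # decoy kind -> compound_id
    table_counts: dict[str, int]
    compound_names: dict[str, str]

    def to_json(self) -> str:
        d = asdict(self)
        d["true_vocs"] = {k: list(v) for k, v in self.true_vocs.items()}
        return json.dumps(d, indent=2, sort_keys=True)


# ---- generation ---------------------------------------------------------


def _mol_props(smiles: str) -> tuple[str, float]:
    mol = Chem.MolFromSmiles(smiles)
    return rdMolDescriptors.CalcMolFormula(mol), float(Descriptors.MolWt(mol))


def _ec_id(i: int) -> str:
    return f"{1 + i % 6}.{1 + (i // 6) % 9}.{1 + (i // 54) % 9}.{i + 1}"


def generate_universe(
    config: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Universe, TruthSet]:
    """Generate a universe with planted ground truth; optionally write the
    TSV tables plus ``truth_manifest.json`` to ``out_dir``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.planted

    # -- compounds -------------------------------------------------------
    compounds: dict[str, U.CompoundRecord] = {}
    name_to_cid: dict[str, str] = {}
    next_cid = 1

    def add_compound(name: str, smiles: str | None) -> str:
        nonlocal next_cid
        cid = f"C{next_cid:05d}"
        next_cid += 1
        if smiles:
            formula, mass = _mol_props(smiles)
        else:
            formula, mass = None, None
        compounds[cid] = U.CompoundRecord(cid, name, smiles, formula, mass)
        name_to_cid.setdefault(name, cid)
        return cid

    for t in _TEMPLATES:
        add_compound(t.name, t.smiles)
    # background compounds: simple generated aliphatics of varied size
    suffixes = ["", "O", "C(O)=O", "N", "C=O", "OC"]
    n_background_cpds = config.n_compounds - len(_TEMPLATES)
    for i in range(n_background_cpds):
        if rng.random() < 0.35:
            # sugar-like polyols: low or nonvolatile, as in real metabolomes
            k = int(rng.integers(2, 12))
            smiles = "OC" + "C(O)" * k + "CO"
        else:
            n = int(rng.integers(2, 16))
            smiles = "C" * n + suffixes[int(rng.integers(0, len(suffixes)))]
        add_compound(f"background-{i:04d}", smiles)
    background_cids = [c for c in compounds if compounds[c].name.startswith("background-")]

    true_voc_names = _TRUE_VOC_CANDIDATES[: p.n_true_vocs]
    true_voc_cids = [name_to_cid[n] for n in true_voc_names]
    decoy_cids = {kind: name_to_cid[nm] for kind, nm in _DECOY_COMPOUNDS.items()}

    # -- studies per planted enzyme pair ---------------------------------
    # Each true VOC gets two enzymes; both carry >= 4 studies.
    def sample_studies(k_lo: int, k_hi: int) -> frozenset[str]:
        k = int(rng.integers(k_lo, k_hi + 1))
        idx = rng.choice(len(STUDIES), size=k, replace=False)
        return frozenset(STUDIES[i] for i in sorted(idx))

    # -- planted enzymes, cogs, kos, reactions, pathways -----------------
    enzymes: dict[str, U.EnzymeEntry] = {}
    reactions: dict[str, U.Reaction] = {}
    cogs: dict[str, U.OrthologGroup] = {}
    kos: dict[str, U.KOEntry] = {}
    proteins: dict[str, U.ProteinRecord] = {}

    ec_reactions: dict[str, set[str]] = {}
    ec_pathways: dict[str, set[str]] = {}
    pathway_members: dict[str, set[str]] = {}
    enriched_ids = [f"P{i + 1:03d}" for i in range(p.n_enriched_pathways)]
    all_pathway_ids = [f"P{i + 1:03d}" for i in range(config.n_pathways)]
    for pid in all_pathway_ids:
        pathway_members[pid] = set()

    next_rxn = 1

    def add_reaction(ec: str, substrates: list[str], products: list[str],
                     reversible: bool = False) -> str:
        nonlocal next_rxn
        rid = f"R{next_rxn:05d}"
        next_rxn += 1
        reactions[rid] = U.Reaction(rid, frozenset(substrates), frozenset(products),
                                    reversible)
        ec_reactions.setdefault(ec, set()).add(rid)
        return rid

    next_protein = 1

    def add_proteins(ec: str, domains: list[str]) -> list[str]:
        nonlocal next_protein
        ids = []
        for dom in domains:
            pid = f"SP{next_protein:05d}"
            next_protein += 1
            proteins[pid] = U.ProteinRecord(pid, frozenset({ec}), dom)
            ids.append(pid)
        return ids

    planted_ec_ids = [_ec_id(i) for i in range(p.n_luca_ecs)]
    decoy_ec_ids = {
        kind: _ec_id(p.n_luca_ecs + j) for j, kind in enumerate(_DECOY_EC_KINDS)
    }
    n_planted_total = p.n_luca_ecs + len(_DECOY_EC_KINDS)
    background_ec_ids = [
        _ec_id(i) for i in range(n_planted_total, config.n_ecs)
    ]

    # KO placement bookkeeping: ko -> list of (domain, phylum-index) demands
    ko_placement: dict[str, list[tuple[str, int]]] = {}

    def place_ko_prokaryotic(ko_id: str, noisy: bool) -> None:
        """Demand >= 2 phyla in each prokaryotic domain; under noise the
        archaeal demand collapses to a single phylum (criterion fails)."""
        nb = config.n_phyla_per_domain["Bacteria"]
        na = config.n_phyla_per_domain["Archaea"]
        b_phyla = rng.choice(nb, size=2, replace=False)
        a_phyla = rng.choice(na, size=2, replace=False)
        demands = [("Bacteria", int(b_phyla[0])), ("Bacteria", int(b_phyla[1]))]
        if noisy:
            demands.append(("Archaea", int(a_phyla[0])))
        else:
            demands += [("Archaea", int(a_phyla[0])), ("Archaea", int(a_phyla[1]))]
        ko_placement[ko_id] = demands

    next_cog = 1
    next_ko = 1

    def add_planted_enzyme(
        ec: str,
        studies: frozenset[str],
        fails_domain_span: bool = False,
        fails_phyla_span: bool = False,
        eukaryote_only: bool = False,
    ) -> None:
        """A planted enzyme with its own COG, proteins and KO."""
        nonlocal next_cog, next_ko
        cog_id = f"COG{next_cog:04d}"
        next_cog += 1
        ko_id = f"K{next_ko:05d}"
        next_ko += 1
        domains = ["Bacteria", "Archaea"] if fails_domain_span else \
            ["Bacteria", "Archaea", "Eukaryota"]
        protein_ids = add_proteins(ec, domains)
        cogs[cog_id] = U.OrthologGroup(
            cog_id, studies, frozenset({ko_id}), frozenset(protein_ids)
        )
        kos[ko_id] = U.KOEntry(ko_id, frozenset({cog_id}), frozenset({ec}))
        if eukaryote_only:
            ko_placement[ko_id] = [("Eukaryota", 0), ("Eukaryota", 1)]
        elif fails_phyla_span:
            nb = config.n_phyla_per_domain["Bacteria"]
            b = rng.choice(nb, size=3, replace=False)
            ko_placement[ko_id] = [("Bacteria", int(i)) for i in b] + [("Archaea", 0)]
        else:
            noisy = bool(rng.random() < p.distribution_noise)
            place_ko_prokaryotic(ko_id, noisy)

    # true VOCs: two enzymes each, concentrated in the enriched pathways
    voc_pair_ecs: dict[str, tuple[str, str]] = {}
    true_voc_studies: dict[str, frozenset[str]] = {}
    for v, cid in enumerate(true_voc_cids):
        e1, e2 = planted_ec_ids[2 * v], planted_ec_ids[2 * v + 1]
        pw = enriched_ids[v % p.n_enriched_pathways]
        studies = sample_studies(4, 6)
        true_voc_studies[cid] = studies
        for ec in (e1, e2):
            add_planted_enzyme(ec, studies)
            co_products = [background_cids[int(rng.integers(0, len(background_cids)))]]
            add_reaction(ec, [cid], co_products, reversible=False)
            ec_pathways.setdefault(ec, set()).add(pw)
            pathway_members[pw].add(ec)
        voc_pair_ecs[cid] = (e1, e2)

    # remaining planted enzymes: most reinforce the enriched pathways,
    # a few live in ordinary pathways (incl. the putrescine-style decoy)
    rest = planted_ec_ids[2 * p.n_true_vocs:]
    n_outside = min(4, len(rest))
    inside, outside = rest[: len(rest) - n_outside], rest[len(rest) - n_outside:]
    for j, ec in enumerate(inside):
        pw = enriched_ids[j % p.n_enriched_pathways]
        add_planted_enzyme(ec, sample_studies(1, 3))
        subs = [background_cids[int(rng.integers(0, len(background_cids)))]]
        add_reaction(ec, subs, [name_to_cid["water"]])
        ec_pathways.setdefault(ec, set()).add(pw)
        pathway_members[pw].add(ec)

    non_enriched_ids = all_pathway_ids[p.n_enriched_pathways:]
    for j, ec in enumerate(outside):
        pw = non_enriched_ids[j % max(1, len(non_enriched_ids))]
        # putrescine-style decoy: full ancestral support, broad studies,
        # but the linking pathway is not enriched
        if j < 2:
            add_planted_enzyme(ec, sample_studies(4, 6))
            add_reaction(ec, [decoy_cids["non_enriched_pathway"]],
                         [name_to_cid["ammonia"]])
        elif j == 2:
            # few-studies decoy: enriched pathway but narrow study support
            pw = enriched_ids[0]
            add_planted_enzyme(ec, sample_studies(2, 3))
            add_reaction(ec, [decoy_cids["few_studies"]], [name_to_cid["water"]])
        else:
            add_planted_enzyme(ec, sample_studies(1, 3))
            subs = [background_cids[int(rng.integers(0, len(background_cids)))]]
            add_reaction(ec, subs, [name_to_cid["water"]])
        ec_pathways.setdefault(ec, set()).add(pw)
        pathway_members[pw].add(ec)

    # decoys that exercise the remaining criteria, attached to a
    # broad-study true-VOC enzyme inside the first enriched pathway so
    # that each fails exactly its own criterion
    pw0 = enriched_ids[0]
    voc0_ec = planted_ec_ids[0]  # first VOC's first enzyme: >= 4 studies, in pw0
    for cid in (decoy_cids["inorganic"], decoy_cids["low_volatility"],
                decoy_cids["no_emission"]):
        add_reaction(voc0_ec, [cid], [name_to_cid["water"]])

    # translation-route decoy enzymes (never reach the common list)
    ec = decoy_ec_ids["fails_domain_span"]
    add_planted_enzyme(ec, sample_studies(4, 6), fails_domain_span=True)
    add_reaction(ec, [decoy_cids["method2_only"]], [name_to_cid["water"]])
    ec_pathways.setdefault(ec, set()).add(pw0)
    pathway_members[pw0].add(ec)

    ec = decoy_ec_ids["fails_phyla_span"]
    add_planted_enzyme(ec, sample_studies(4, 6), fails_phyla_span=True)
    add_reaction(ec, [decoy_cids["method1_only"]], [name_to_cid["water"]])
    ec_pathways.setdefault(ec, set()).add(pw0)
    pathway_members[pw0].add(ec)

    ec = decoy_ec_ids["eukaryote_only_ko"]
    add_planted_enzyme(ec, sample_studies(1, 2), eukaryote_only=True)
    subs = [background_cids[int(rng.integers(0, len(background_cids)))]]
    add_reaction(ec, subs, [name_to_cid["water"]])

    # -- background enzymes, kos, reactions ------------------------------
    n_bg_kos = config.n_kos - next_ko + 1
    bg_ko_ids = [f"K{next_ko + i:05d}" for i in range(n_bg_kos)]
    for i, ko_id in enumerate(bg_ko_ids):
        ec_choices = rng.choice(len(background_ec_ids),
                                size=min(2, len(background_ec_ids)), replace=False)
        kos[ko_id] = U.KOEntry(
            ko_id, frozenset(),
            frozenset(background_ec_ids[int(j)] for j in ec_choices),
        )

    for ec in background_ec_ids:
        n_rxn = int(rng.integers(1, 3))
        for _ in range(n_rxn):
            if len(reactions) >= config.n_reactions:
                break
            k_sub = int(rng.integers(1, 4))
            k_prod = int(rng.integers(1, 3))
            subs = [background_cids[int(j)]
                    for j in rng.integers(0, len(background_cids), size=k_sub)]
            prods = [background_cids[int(j)]
                     for j in rng.integers(0, len(background_cids), size=k_prod)]
            if rng.random() < p.background_link_density:
                prods.append(background_cids[int(rng.integers(0, len(background_cids)))])
            add_reaction(ec, sorted(set(subs)), sorted(set(prods)),
                         reversible=bool(rng.random() < 0.3))
        # a share of background enzymes also gets domain-spanning proteins
        # (they are never COG-linked, so neither route can accept them)
        if rng.random() < 0.3:
            add_proteins(ec, ["Bacteria", "Eukaryota"])

    # assign background enzymes to the ordinary pathways
    for pid in non_enriched_ids:
        size = int(rng.integers(8, 14))
        picks = rng.choice(len(background_ec_ids), size=min(size, len(background_ec_ids)),
                           replace=False)
        for j in picks:
            ec = background_ec_ids[int(j)]
            pathway_members[pid].add(ec)
            ec_pathways.setdefault(ec, set()).add(pid)
    # pad enriched pathways with a few background enzymes
    for pid in enriched_ids:
        picks = rng.choice(len(background_ec_ids), size=4, replace=False)
        for j in picks:
            ec = background_ec_ids[int(j)]
            pathway_members[pid].add(ec)
            ec_pathways.setdefault(ec, set()).add(pid)

    for ec in planted_ec_ids + list(decoy_ec_ids.values()) + background_ec_ids:
        enzymes[ec] = U.EnzymeEntry(
            ec,
            frozenset(ec_reactions.get(ec, set())),
            frozenset(ec_pathways.get(ec, set())),
        )

    pathways = {}
    for pid in all_pathway_ids:
        members = pathway_members[pid]
        if not members:  # pathways must be non-empty; backfill one enzyme
            ec = background_ec_ids[0]
            members = {ec}
            enzymes[ec] = U.EnzymeEntry(
                ec, enzymes[ec].reaction_ids, enzymes[ec].pathway_ids | {pid}
            )
        scope: set[str] = set()
        for ec in members:
            scope |= enzymes[ec].reaction_ids
        pathways[pid] = U.Pathway(pid, f"pathway {pid}", frozenset(members),
                                  frozenset(scope))

    # -- genomes ---------------------------------------------------------
    genomes: dict[str, U.Genome] = {}
    genome_grid: dict[tuple[str, int], list[str]] = {}
    gi = 1
    for dom in ("Bacteria", "Archaea", "Eukaryota"):
        n_g = config.n_genomes_per_domain[dom]
        n_p = config.n_phyla_per_domain[dom]
        for k in range(n_g):
            phylum_idx = k % n_p
            gid = f"G{gi:04d}"
            gi += 1
            genome_grid.setdefault((dom, phylum_idx), []).append(gid)
            genomes[gid] = U.Genome(gid, dom, f"{dom[:3]}-phylum-{phylum_idx}",
                                    frozenset())

    genome_kos: dict[str, set[str]] = {g: set() for g in genomes}
    # planted KO placement: one genome per demanded (domain, phylum)
    for ko_id, demands in ko_placement.items():
        for dom, phylum_idx in demands:
            pool = genome_grid[(dom, phylum_idx % config.n_phyla_per_domain[dom])]
            gid = pool[int(rng.integers(0, len(pool)))]
            genome_kos[gid].add(ko_id)
    # background KOs scattered at random
    gids = sorted(genomes)
    for ko_id in bg_ko_ids:
        n_hits = int(rng.integers(1, 6))
        for j in rng.integers(0, len(gids), size=n_hits):
            genome_kos[gids[int(j)]].add(ko_id)
    genomes = {
        gid: U.Genome(g.genome_id, g.domain, g.phylum, frozenset(genome_kos[gid]))
        for gid, g in genomes.items()
    }

    # -- emissions and taxonomy ------------------------------------------
    emissions: dict[str, U.EmissionRecord] = {}
    confirmed = set(true_voc_cids) | {
        decoy_cids["inorganic"], decoy_cids["low_volatility"],
        decoy_cids["non_enriched_pathway"], decoy_cids["few_studies"],
        decoy_cids["method1_only"], decoy_cids["method2_only"],
    }
    for cid in sorted(confirmed):
        emissions[cid] = U.EmissionRecord(cid, True, "synthetic emission evidence")

    chem_taxonomy = {
        cid: _classify_synthetic(compounds[cid])
        for cid in sorted(compounds)
    }

    uni = Universe(
        cogs=cogs, proteins=proteins, kos=kos, genomes=genomes,
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        pathways=pathways, emissions=emissions, chem_taxonomy=chem_taxonomy,
    )

    truth = TruthSet(
        luca_cogs=tuple(sorted(cogs)[: p.n_luca_ecs]),
        luca_ecs=tuple(planted_ec_ids),
        enriched_pathways=tuple(enriched_ids),
        true_vocs={cid: tuple(sorted(true_voc_studies[cid])) for cid in true_voc_cids},
        decoys=dict(sorted(decoy_cids.items())),
        table_counts={
            "cogs": len(cogs), "proteins": len(proteins), "kos": len(kos),
            "genomes": len(genomes), "enzymes": len(enzymes),
            "reactions": len(reactions), "compounds": len(compounds),
            "pathways": len(pathways),
        },
        compound_names={cid: compounds[cid].name
                        for cid in list(true_voc_cids) + sorted(decoy_cids.values())},
    )

    if out_dir is not None:
        out = Path(out_dir)
        U.write_universe(uni, out)
        (out / "truth_manifest.json").write_text(truth.to_json(), encoding="utf-8")
    return uni, truth


# fixed, deliberately coarse taxonomy for synthetic compounds
_TAXONOMY_RULES = [
    ("carboxylic_acid", ("Organic acids and derivatives",
                         "Carboxylic acids and derivatives",
                         "Carboxylic acids")),
    ("amide", ("Organic acids and derivatives", "Carboxylic acids and derivatives",
               "Amides")),
    ("ester", ("Organic acids and derivatives", "Carboxylic acids and derivatives",
               "Esters")),
    ("aldehyde", ("Organic oxygen compounds", "Organooxygen compounds",
                  "Carbonyl compounds")),
    ("ketone", ("Organic oxygen compounds", "Organooxygen compounds",
                "Carbonyl compounds")),
    ("hydroxyl", ("Organic oxygen compounds", "Organooxygen compounds",
                  "Alcohols and polyols")),
    ("phenol", ("Benzenoids", "Phenols", "Phenols")),
    ("ether", ("Organic oxygen compounds", "Organooxygen compounds", "Ethers")),
    ("amine_primary", ("Organic nitrogen compounds", "Organonitrogen compounds",
                       "Amines")),
    ("amine_secondary", ("Organic nitrogen compounds", "Organonitrogen compounds",
                         "Amines")),
    ("amine_tertiary", ("Organic nitrogen compounds", "Organonitrogen compounds",
                        "Amines")),
    ("nitro", ("Organic nitrogen compounds", "Organonitrogen compounds",
               "Nitro compounds")),
    ("aromatic_ring", ("Benzenoids", "Benzene and substituted derivatives",
                       "Benzene derivatives")),
]


def _classify_synthetic(record: U.CompoundRecord) -> U.Classification:
    from .volatility import count_functional_groups

    cid = record.compound_id
    if not record.smiles:
        return U.Classification(cid, "unclassified", "unclassified", "unclassified")
    gc = count_functional_groups(record.smiles)
    if gc.get("carbon") == 0:
        return U.Classification(cid, "Inorganic compounds", "Other non-metal compounds",
                                "Inorganic molecular entities")
    for kind, (sup, klass, sub) in _TAXONOMY_RULES:
        if gc.get(kind):
            return U.Classification(cid, sup, klass, sub)
    return U.Classification(cid, "Hydrocarbons", "Saturated hydrocarbons", "Alkanes")


# ---- funnel fixture -----------------------------------------------------


def funnel_universe(
    n_common: int = 206,
    n_inorganic: int = 20,
    n_emitted: int = 27,
    n_enriched_supported: int = 9,
    n_final: int = 7,
) -> tuple[Universe, "CommonListLike"]:
    """A hand-shaped universe whose conservative-filter funnel has the
    prescribed stage sizes (defaults 206 -> 186 -> 27 -> 9 -> 7).

    All ``n_common`` compounds are high-volatility; ``n_inorganic`` of
    them are carbon-free; of the organic remainder ``n_emitted`` are
    emission-confirmed; of those ``n_enriched_supported`` are linked to
    an ancestral enzyme through a reaction inside an enriched pathway;
    and of those ``n_final`` carry at least four supporting studies.
    Returns the universe plus a ready common list.
    """
    from .translate import CommonList, Provenance

    if not n_common >= n_common - n_inorganic >= n_emitted >= n_enriched_supported >= n_final >= 0:
        raise ConfigError("funnel stage sizes must be weakly decreasing")

    compounds: dict[str, U.CompoundRecord] = {}
    cids = [f"F{i:04d}" for i in range(n_common)]
    for i, cid in enumerate(cids):
        if i < n_inorganic:
            smiles = "O" if i % 2 == 0 else "N"  # water / ammonia-like
            name = f"inorganic-{i}"
        else:
            smiles = "CCO" if i % 2 == 0 else "CC=O"  # small, surely volatile
            name = f"organic-{i}"
        formula, mass = _mol_props(smiles)
        compounds[cid] = U.CompoundRecord(cid, name, smiles, formula, mass)

    organic = cids[n_inorganic:]
    emitted = set(organic[:n_emitted])
    supported = organic[:n_enriched_supported]
    final = set(organic[:n_final])

    # one ancestral enzyme inside an enriched pathway links the supported
    # compounds; a second enzyme outside it links everything else
    ec_in, ec_out, ec_pad1, ec_pad2 = "1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4"
    reactions: dict[str, U.Reaction] = {}
    ec_rxns: dict[str, set[str]] = {ec_in: set(), ec_out: set(),
                                    ec_pad1: set(), ec_pad2: set()}
    for i, cid in enumerate(cids):
        ec = ec_in if cid in set(supported) else ec_out
        rid = f"FR{i:04d}"
        reactions[rid] = U.Reaction(rid, frozenset({cid}), frozenset(), False)
        ec_rxns[ec].add(rid)

    enriched_pw = U.Pathway(
        "PW-enriched", "enriched pathway",
        frozenset({ec_in, ec_pad1, ec_pad2}),
        frozenset(ec_rxns[ec_in]),
    )
    other_pw = U.Pathway(
        "PW-other", "ordinary pathway", frozenset({ec_out}), frozenset(ec_rxns[ec_out])
    )
    enzymes = {
        ec_in: U.EnzymeEntry(ec_in, frozenset(ec_rxns[ec_in]), frozenset({"PW-enriched"})),
        ec_out: U.EnzymeEntry(ec_out, frozenset(ec_rxns[ec_out]), frozenset({"PW-other"})),
        ec_pad1: U.EnzymeEntry(ec_pad1, frozenset(), frozenset({"PW-enriched"})),
        ec_pad2: U.EnzymeEntry(ec_pad2, frozenset(), frozenset({"PW-enriched"})),
    }
    # background enzymes so that the enriched pathway is actually enriched
    for i in range(26):
        ec = f"5.5.5.{i + 1}"
        enzymes[ec] = U.EnzymeEntry(ec, frozenset(), frozenset())

    emissions = {cid: U.EmissionRecord(cid, True, "fixture") for cid in sorted(emitted)}
    taxonomy = {cid: U.Classification(cid, "fixture", "fixture", "fixture")
                for cid in cids}

    uni = Universe(
        cogs={}, proteins={}, kos={}, genomes={},
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        pathways={"PW-enriched": enriched_pw, "PW-other": other_pw},
        emissions=emissions, chem_taxonomy=taxonomy,
    )

    many = frozenset(STUDIES[:5])
    few = frozenset(STUDIES[:3])
    # the enzyme inside the enriched pathway carries broad study support;
    # compounds beyond n_final are additionally linked through a
    # narrow-support enzyme only
    prov = {
        ec_in: Provenance(frozenset({"COG-in"}), many),
        ec_out: Provenance(frozenset({"COG-out"}), few),
        ec_pad1: Provenance(frozenset({"COG-pad1"}), many),
        ec_pad2: Provenance(frozenset({"COG-pad2"}), many),
    }
    # move the supported-but-few-studies compounds onto a narrow variant:
    # compounds in `supported` but not `final` must count < 4 studies, so
    # they get their own enzyme with few studies inside the pathway
    if n_enriched_supported > n_final:
        ec_narrow = "6.6.6.6"
        narrow_rxns = set()
        new_reactions = dict(reactions)
        for cid in supported[n_final:]:
            # relink: remove from ec_in, attach to ec_narrow
            rids = [r for r, rx in reactions.items() if cid in rx.substrate_ids]
            narrow_rxns.update(rids)
        in_rxns = ec_rxns[ec_in] - narrow_rxns
        enzymes[ec_in] = U.EnzymeEntry(ec_in, frozenset(in_rxns),
                                       frozenset({"PW-enriched"}))
        enzymes[ec_narrow] = U.EnzymeEntry(ec_narrow, frozenset(narrow_rxns),
                                           frozenset({"PW-enriched"}))
        prov[ec_narrow] = Provenance(frozenset({"COG-narrow"}), few)
        pw = U.Pathway("PW-enriched", "enriched pathway",
                       frozenset({ec_in, ec_narrow, ec_pad1, ec_pad2}),
                       frozenset(ec_rxns[ec_in]))
        uni = Universe(
            cogs={}, proteins={}, kos={}, genomes={},
            enzymes=enzymes, reactions=new_reactions, compounds=compounds,
            pathways={"PW-enriched": pw, "PW-other": other_pw},
            emissions=emissions, chem_taxonomy=taxonomy,
        )

    common = CommonList(ecs=prov, compounds=set(cids))
    return uni, common
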