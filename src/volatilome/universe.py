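"""Relational knowledge universe: ortholog groups, enzymes, reactions, compounds, pathways.

The universe is the in-memory join of a directory of UTF-8 tab-separated
tables (``cogs.tsv``, ``proteins.tsv``, ``kos.tsv``, ``genomes.tsv``,
``enzymes.tsv``, ``reactions.tsv``, ``compounds.tsv``, ``pathways.tsv``,
``emissions.tsv``, ``chem_taxonomy.tsv``).  Multi-valued cells are
semicolon-separated id lists.  Loading enforces referential integrity
(every foreign id must resolve) and primary-key uniqueness; the loaded
object is immutable and all query methods are pure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of the eight ancestral-reconstruction studies whose
#: ortholog-group calls the pipeline aggregates.
STUDY_LABELS = frozenset(
    {"Delaye", "Harris", "Mirkin", "Ranea", "Srinivasan", "Wang", "Weiss", "Yang"}
)

DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota"})

TABLE_FILES = {
    "cogs": "cogs.tsv",
    "proteins": "proteins.tsv",
    "kos": "kos.tsv",
    "genomes": "genomes.tsv",
    "enzymes": "enzymes.tsv",
    "reactions": "reactions.tsv",
    "compounds": "compounds.tsv",
    "pathways": "pathways.tsv",
    "emissions": "emissions.tsv",
    "chem_taxonomy": "chem_taxonomy.tsv",
}


class UniverseError(ValueError):
    """Raised on malformed or referentially inconsistent universe tables."""


@dataclass(frozen=True)
class OrthologGroup:
    cog_id: str
    source_studies: frozenset[str]
    linked_ko_ids: frozenset[str]
    linked_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.source_studies:
            raise UniverseError(f"{self.cog_id}: source_studies must be non-empty")
        bad = self.source_studies - STUDY_LABELS
        if bad:
            raise UniverseError(f"{self.cog_id}: unknown study labels {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    ec_numbers: frozenset[str]
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise UniverseError(f"{self.protein_id}: invalid domain {self.domain!r}")


@dataclass(frozen=True)
class KOEntry:
    ko_id: str
    linked_cog_ids: frozenset[str]
    ec_numbers: frozenset[str]


@dataclass(frozen=True)
class Genome:
    genome_id: str
    domain: str
    phylum: str
    ko_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise UniverseError(f"{self.genome_id}: invalid domain {self.domain!r}")
        if not self.phylum:
            raise UniverseError(f"{self.genome_id}: phylum must be non-empty")


def is_valid_ec(ec: str) -> bool:
    """Four dot-separated fields; the last may be a dash placeholder."""
    parts = ec.split(".")
    if len(parts) != 4:
        return False
    head, last = parts[:3], parts[3]
    return all(p.isdigit() for p in head) and (last.isdigit() or last == "-")


@dataclass(frozen=True)
class EnzymeEntry:
    ec_number: str
    reaction_ids: frozenset[str]
    pathway_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not is_valid_ec(self.ec_number):
            raise UniverseError(f"invalid EC number {self.ec_number!r}")


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrate_ids: frozenset[str]
    product_ids: frozenset[str]
    reversible: bool

    def __post_init__(self) -> None:
        if not (self.substrate_ids | self.product_ids):
            raise UniverseError(f"{self.reaction_id}: no substrates or products")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    smiles: str | None
    formula: str | None
    molar_mass: float | None
    inchikey: str | None = None

    def __post_init__(self) -> None:
        if self.molar_mass is not None and not self.molar_mass > 0:
            raise UniverseError(f"{self.compound_id}: molar_mass must be > 0")


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    ec_numbers: frozenset[str]
    # Optional explicit reaction scope; empty means "derive from member enzymes".
    reaction_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ec_numbers:
            raise UniverseError(f"{self.pathway_id}: ec_numbers must be non-empty")


@dataclass(frozen=True)
class EmissionRecord:
    compound_id: str
    confirmed: bool
    source: str = ""


@dataclass(frozen=True)
class Classification:
    compound_id: str
    superclass: str
    klass: str
    subclass: str


@dataclass(frozen=True)
class Universe:
    """Immutable, cross-validated knowledge universe."""

    cogs: Mapping[str, OrthologGroup]
    proteins: Mapping[str, ProteinRecord]
    kos: Mapping[str, KOEntry]
    genomes: Mapping[str, Genome]
    enzymes: Mapping[str, EnzymeEntry]
    reactions: Mapping[str, Reaction]
    compounds: Mapping[str, CompoundRecord]
    pathways: Mapping[str, Pathway]
    emissions: Mapping[str, EmissionRecord]
    chem_taxonomy: Mapping[str, Classification]

    # ---- queries -------------------------------------------------------

    def compounds_for_enzyme(self, ec: str, substrates_only: bool = False) -> set[str]:
        """Compounds associated with an enzyme: substrates of its reactions,
        plus products of reactions flagged reversible (unless
        ``substrates_only``)."""
        enzyme = self.enzymes.get(ec)
        if enzyme is None:
            raise KeyError(f"unknown EC number {ec!r}")
        out: set[str] = set()
        for rid in enzyme.reaction_ids:
            rxn = self.reactions[rid]
            out |= rxn.substrate_ids
            if rxn.reversible and not substrates_only:
                out |= rxn.product_ids
        return out

    def pathways_for_enzyme(self, ec: str) -> set[str]:
        enzyme = self.enzymes.get(ec)
        if enzyme is None:
            raise KeyError(f"unknown EC number {ec!r}")
        return set(enzyme.pathway_ids)

    def enzymes_for_pathway(self, pathway_id: str) -> set[str]:
        pathway = self.pathways.get(pathway_id)
        if pathway is None:
            raise KeyError(f"unknown pathway {pathway_id!r}")
        return set(pathway.ec_numbers)

    def pathway_reaction_scope(self, pathway_id: str) -> set[str]:
        """Reactions considered part of a pathway.

        Uses the explicit ``reaction_ids`` column when present; otherwise
        falls back to the union of the member enzymes' reactions.
        """
        pathway = self.pathways.get(pathway_id)
        if pathway is None:
            raise KeyError(f"unknown pathway {pathway_id!r}")
        if pathway.reaction_ids:
            return set(pathway.reaction_ids)
        scope: set[str] = set()
        for ec in pathway.ec_numbers:
            if ec in self.enzymes:
                scope |= self.enzymes[ec].reaction_ids
        return scope

    def kos_with_ec(self, ec: str) -> set[str]:
        return {k.ko_id for k in self.kos.values() if ec in k.ec_numbers}

    def genomes_with_ko(self, ko_id: str) -> list[Genome]:
        return [g for g in self.genomes.values() if ko_id in g.ko_ids]


# ---- TSV (de)serialization ---------------------------------------------


def _split(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def _join(items: Iterable[str]) -> str:
    return ";".join(sorted(items))


def _read(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise UniverseError(f"missing universe table: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _check_unique(df: pd.DataFrame, col: str, table: str) -> None:
    dup = df[col][df[col].duplicated()]
    if len(dup):
        raise UniverseError(f"{table}: duplicate primary id(s) {sorted(set(dup))}")


def load_universe(directory: str | Path) -> Universe:
    """Load and cross-validate all universe tables from ``directory``.

    Raises :class:`UniverseError` on a missing file, duplicate primary id,
    or dangling foreign id (the error names the offending rows).
    """
    d = Path(directory)
    frames = {name: _read(d / fname) for name, fname in TABLE_FILES.items()}

    for name, key in [
        ("cogs", "cog_id"), ("proteins", "protein_id"), ("kos", "ko_id"),
        ("genomes", "genome_id"), ("enzymes", "ec_number"),
        ("reactions", "reaction_id"), ("compounds", "compound_id"),
        ("pathways", "pathway_id"),
    ]:
        _check_unique(frames[name], key, name)

    compounds = {
        r.compound_id: CompoundRecord(
            compound_id=r.compound_id,
            name=r.name,
            smiles=r.smiles or None,
            formula=r.formula or None,
            molar_mass=float(r.molar_mass) if r.molar_mass else None,
            inchikey=getattr(r, "inchikey", "") or None,
        )
        for r in frames["compounds"].itertuples(index=False)
    }
    reactions = {
        r.reaction_id: Reaction(
            reaction_id=r.reaction_id,
            substrate_ids=_split(r.substrate_ids),
            product_ids=_split(r.product_ids),
            reversible=str(r.reversible).lower() in {"true", "1", "yes"},
        )
        for r in frames["reactions"].itertuples(index=False)
    }
    enzymes = {
        r.ec_number: EnzymeEntry(
            ec_number=r.ec_number,
            reaction_ids=_split(r.reaction_ids),
            pathway_ids=_split(r.pathway_ids),
        )
        for r in frames["enzymes"].itertuples(index=False)
    }
    pathways = {
        r.pathway_id: Pathway(
            pathway_id=r.pathway_id,
            name=r.name,
            ec_numbers=_split(r.ec_numbers),
            reaction_ids=_split(getattr(r, "reaction_ids", "")),
        )
        for r in frames["pathways"].itertuples(index=False)
    }
    proteins = {
        r.protein_id: ProteinRecord(
            protein_id=r.protein_id,
            ec_numbers=_split(r.ec_numbers),
            domain=r.domain,
        )
        for r in frames["proteins"].itertuples(index=False)
    }
    kos = {
        r.ko_id: KOEntry(
            ko_id=r.ko_id,
            linked_cog_ids=_split(r.linked_cog_ids),
            ec_numbers=_split(r.ec_numbers),
        )
        for r in frames["kos"].itertuples(index=False)
    }
    cogs = {
        r.cog_id: OrthologGroup(
            cog_id=r.cog_id,
            source_studies=_split(r.source_studies),
            linked_ko_ids=_split(r.linked_ko_ids),
            linked_protein_ids=_split(r.linked_protein_ids),
        )
        for r in frames["cogs"].itertuples(index=False)
    }
    genomes = {
        r.genome_id: Genome(
            genome_id=r.genome_id,
            domain=r.domain,
            phylum=r.phylum,
            ko_ids=_split(r.ko_ids),
        )
        for r in frames["genomes"].itertuples(index=False)
    }
    emissions = {
        r.compound_id: EmissionRecord(
            compound_id=r.compound_id,
            confirmed=str(r.confirmed).lower() in {"true", "1", "yes"},
            source=getattr(r, "source", ""),
        )
        for r in frames["emissions"].itertuples(index=False)
    }
    # chem_taxonomy columns: compound_id, superclass, class, subclass.
    # "class" is a keyword, so itertuples renames it; index positionally.
    chem_taxonomy: dict[str, Classification] = {}
    for row in frames["chem_taxonomy"].itertuples(index=False):
        cid, superclass, klass, subclass = row[0], row[1], row[2], row[3]
        chem_taxonomy[cid] = Classification(cid, superclass, klass, subclass)

    uni = Universe(
        cogs=cogs, proteins=proteins, kos=kos, genomes=genomes,
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        pathways=pathways, emissions=emissions, chem_taxonomy=chem_taxonomy,
    )
    violations = _integrity_violations(uni)
    if violations:
        raise UniverseError(
            "referential integrity violations:\n  " + "\n  ".join(violations)
        )
    logger.info(
        "loaded universe: %d cogs, %d proteins, %d kos, %d genomes, %d enzymes, "
        "%d reactions, %d compounds, %d pathways",
        len(cogs), len(proteins), len(kos), len(genomes), len(enzymes),
        len(reactions), len(compounds), len(pathways),
    )
    return uni


def _integrity_violations(u: Universe) -> list[str]:
    v: list[str] = []
    for cog in u.cogs.values():
        for ko in cog.linked_ko_ids - u.kos.keys():
            v.append(f"cog {cog.cog_id}: unknown KO {ko}")
        for pid in cog.linked_protein_ids - u.proteins.keys():
            v.append(f"cog {cog.cog_id}: unknown protein {pid}")
    for ko in u.kos.values():
        for cid in ko.linked_cog_ids - u.cogs.keys():
            v.append(f"ko {ko.ko_id}: unknown COG {cid}")
    for g in u.genomes.values():
        for ko in g.ko_ids - u.kos.keys():
            v.append(f"genome {g.genome_id}: unknown KO {ko}")
    for e in u.enzymes.values():
        for rid in e.reaction_ids - u.reactions.keys():
            v.append(f"enzyme {e.ec_number}: unknown reaction {rid}")
        for pid in e.pathway_ids - u.pathways.keys():
            v.append(f"enzyme {e.ec_number}: unknown pathway {pid}")
    for r in u.reactions.values():
        for cid in (r.substrate_ids | r.product_ids) - u.compounds.keys():
            v.append(f"reaction {r.reaction_id}: unknown compound {cid}")
    for p in u.pathways.values():
        for ec in p.ec_numbers - u.enzymes.keys():
            v.append(f"pathway {p.pathway_id}: unknown enzyme {ec}")
        for rid in p.reaction_ids - u.reactions.keys():
            v.append(f"pathway {p.pathway_id}: unknown reaction {rid}")
    for em in u.emissions.values():
        if em.compound_id not in u.compounds:
            v.append(f"emission record: unknown compound {em.compound_id}")
    for cl in u.chem_taxonomy.values():
        if cl.compound_id not in u.compounds:
            v.append(f"chem_taxonomy: unknown compound {cl.compound_id}")
    return v


def write_universe(u: Universe, directory: str | Path) -> None:
    """Serialize a universe back to its canonical TSV layout.

    Rows are written in sorted primary-key order so that equal universes
    produce byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def dump(name: str, header: list[str], rows: list[list]) -> None:
        df = pd.DataFrame(rows, columns=header)
        df.to_csv(d / TABLE_FILES[name], sep="\t", index=False)

    dump("cogs", ["cog_id", "source_studies", "linked_ko_ids", "linked_protein_ids"],
         [[c.cog_id, _join(c.source_studies), _join(c.linked_ko_ids),
           _join(c.linked_protein_ids)] for c in _sorted(u.cogs)])
    dump("proteins", ["protein_id", "ec_numbers", "domain"],
         [[p.protein_id, _join(p.ec_numbers), p.domain] for p in _sorted(u.proteins)])
    dump("kos", ["ko_id", "linked_cog_ids", "ec_numbers"],
         [[k.ko_id, _join(k.linked_cog_ids), _join(k.ec_numbers)]
          for k in _sorted(u.kos)])
    dump("genomes", ["genome_id", "domain", "phylum", "ko_ids"],
         [[g.genome_id, g.domain, g.phylum, _join(g.ko_ids)]
          for g in _sorted(u.genomes)])
    dump("enzymes", ["ec_number", "reaction_ids", "pathway_ids"],
         [[e.ec_number, _join(e.reaction_ids), _join(e.pathway_ids)]
          for e in _sorted(u.enzymes)])
    dump("reactions", ["reaction_id", "substrate_ids", "product_ids", "reversible"],
         [[r.reaction_id, _join(r.substrate_ids), _join(r.product_ids),
           str(r.reversible).lower()] for r in _sorted(u.reactions)])
    dump("compounds", ["compound_id", "name", "smiles", "formula", "molar_mass",
                       "inchikey"],
         [[c.compound_id, c.name, c.smiles or "", c.formula or "",
           "" if c.molar_mass is None else repr(c.molar_mass), c.inchikey or ""]
          for c in _sorted(u.compounds)])
    dump("pathways", ["pathway_id", "name", "ec_numbers", "reaction_ids"],
         [[p.pathway_id, p.name, _join(p.ec_numbers), _join(p.reaction_ids)]
          for p in _sorted(u.pathways)])
    dump("emissions", ["compound_id", "confirmed", "source"],
         [[e.compound_id, str(e.confirmed).lower(), e.source]
          for e in _sorted(u.emissions)])
    dump("chem_taxonomy", ["compound_id", "superclass", "class", "subclass"],
         [[c.compound_id, c.superclass, c.klass, c.subclass]
          for c in _sorted(u.chem_taxonomy)])


def _sorted(mapping: Mapping[str, object]) -> list:
    return [mapping[k] for k in sorted(mapping)]
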