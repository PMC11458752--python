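"""Group-contribution volatility estimation (SIMPOL.1 style).

Vapor pressure is estimated as

    log10 P(atm) = b0 + sum_k v_k * b_k

where ``v_k`` counts functional groups of kind ``k`` in the molecule and
the ``b_k`` are group-contribution terms at a fixed reference temperature
(293.15 K), shipped in ``data/simpol_coefficients.tsv``.  The estimate is
converted to a saturation mass concentration

    C* = 1e6 * M * P / (R * T)   [ug m^-3]

and binned into a relative volatility index (RVI): nonvolatile
(log10 C* < -2), low (-2 to 0), intermediate (0 to 2) and high (> 2).

Functional groups are counted from SMILES with RDKit SMARTS matching under
a fixed precedence so that every oxygen/nitrogen atom participates in at
most one group (carboxylic acid > ester > amide > aldehyde > ketone >
phenol > hydroxyl > ether; amines by substitution degree).  Heteroatom
features with no coefficient (S, Se, P, halogens, ...) are tallied as
``unmatched_heteroatom`` and contribute zero with a warning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

from .universe import CompoundRecord

RDLogger.DisableLog("rdApp.*")

#: Gas constant in m^3 atm K^-1 mol^-1.
R_ATM = 8.20574e-5

#: Reference temperature (K) for the shipped coefficient table.
DEFAULT_TEMPERATURE = 293.15

UNMATCHED = "unmatched_heteroatom"

GROUP_KINDS = (
    "carbon",
    "aromatic_ring",
    "carbon_double_bond",
    "hydroxyl",
    "aldehyde",
    "ketone",
    "carboxylic_acid",
    "ester",
    "ether",
    "phenol",
    "nitro",
    "amine_primary",
    "amine_secondary",
    "amine_tertiary",
    "amide",
    UNMATCHED,
)


class VolatilityError(ValueError):
    pass


@dataclass(frozen=True)
class GroupCounts:
    """Non-negative functional-group counts for one molecule."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if k not in GROUP_KINDS:
                raise VolatilityError(f"unknown group kind {k!r}")
            if v < 0:
                raise VolatilityError(f"negative count for {k}")

    def get(self, kind: str) -> int:
        return self.counts.get(kind, 0)

    def nonzero(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if v}


@dataclass(frozen=True)
class SimpolCoefficients:
    b0: float
    bk: dict[str, float]
    reference_temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.bk.get("carbon", -1.0) >= 0:
            raise VolatilityError("carbon-number coefficient must be negative")


@dataclass(frozen=True)
class VolatilityResult:
    compound_id: str
    group_counts: GroupCounts | None
    log10_p: float | None
    log10_cstar: float | None
    category: str | None  # nonvolatile / low / intermediate / high
    assessable: bool = True
    warnings: tuple[str, ...] = field(default_factory=tuple)


def load_coefficients(path: str | Path | None = None) -> SimpolCoefficients:
    """Load the group-contribution table (default: packaged coefficients)."""
    if path is None:
        ref = resources.files("volatilome.data") / "simpol_coefficients.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    bk: dict[str, float] = {}
    b0 = None
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        kind, value = line.split("\t")
        if kind == "intercept":
            b0 = float(value)
        else:
            bk[kind] = float(value)
    if b0 is None:
        raise VolatilityError("coefficient table lacks an intercept row")
    return SimpolCoefficients(b0=b0, bk=bk)


# SMARTS patterns in precedence order.  ``core`` lists the match-atom
# indices that are marked consumed (and checked for prior consumption):
# the heteroatoms plus the carbonyl carbon.  Flanking carbons in e.g. the
# ketone pattern are deliberately not core so that an already-assigned
# carboxyl carbon can still flank a ketone (as in phenylpyruvate).
_PATTERNS: list[tuple[str, str, tuple[int, ...]]] = [
    ("carboxylic_acid", "[CX3](=[OX1])[OX2H1]", (0, 1, 2)),
    ("ester", "[CX3](=[OX1])[OX2H0][#6]", (0, 1, 2)),
    ("amide", "[CX3](=[OX1])[NX3]", (0, 1, 2)),
    ("aldehyde", "[CX3;H1,H2]=[OX1]", (0, 1)),
    ("ketone", "[#6][CX3](=[OX1])[#6]", (1, 2)),
    ("phenol", "[OX2H1][c]", (0,)),
    ("hydroxyl", "[OX2H1][CX4]", (0,)),
    ("ether", "[OX2H0]([#6])[#6]", (0,)),
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]", (0,)),
    ("amine_primary", "[NX3;H2;!$([N]C=[OX1])][#6]", (0,)),
    ("amine_secondary", "[NX3;H1;!$([N]C=[OX1])]([#6])[#6]", (0,)),
    ("amine_tertiary", "[NX3;H0;!$([N]C=[OX1]);!$([N+])]([#6])([#6])[#6]", (0,)),
]
_COMPILED = [(name, Chem.MolFromSmarts(s), core) for name, s, core in _PATTERNS]

# Atoms consumed implicitly alongside a nitro nitrogen: its oxygens.
_NITRO_O = Chem.MolFromSmarts("[NX3,NX3+](~[OX1])~[OX1,OX1-]")


def count_functional_groups(smiles: str) -> GroupCounts:
    """Count SIMPOL.1 functional groups in a single-fragment molecule.

    Raises :class:`VolatilityError` for unparseable or multi-fragment
    SMILES.  A molecule with zero carbons is allowed here (it simply has
    ``carbon == 0``); organic/inorganic triage is the filter stage's job.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise VolatilityError(f"unparseable SMILES {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise VolatilityError(f"multi-fragment SMILES {smiles!r}")

    counts = {k: 0 for k in GROUP_KINDS}
    counts["carbon"] = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    counts["aromatic_ring"] = sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    counts["carbon_double_bond"] = sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE
        and not b.GetIsAromatic()
        and b.GetBeginAtom().GetAtomicNum() == 6
        and b.GetEndAtom().GetAtomicNum() == 6
    )

    consumed: set[int] = set()
    for name, patt, core in _COMPILED:
        for match in mol.GetSubstructMatches(patt):
            core_atoms = {match[i] for i in core}
            if core_atoms & consumed:
                continue
            consumed |= core_atoms
            if name == "nitro":
                # also consume the two oxygens so they are not "unmatched"
                n_idx = match[0]
                for nbr in mol.GetAtomWithIdx(n_idx).GetNeighbors():
                    if nbr.GetAtomicNum() == 8:
                        consumed.add(nbr.GetIdx())
            counts[name] += 1

    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (1, 6):
            continue
        if atom.GetIdx() not in consumed:
            counts[UNMATCHED] += 1

    return GroupCounts(counts=counts)


def log10_vapor_pressure(
    gc: GroupCounts, coeffs: SimpolCoefficients
) -> tuple[float, list[str]]:
    """log10 vapor pressure in atm: ``b0 + sum_k v_k b_k``.

    Group kinds with no coefficient contribute zero; each such kind with a
    nonzero count appends a warning.  Returns ``(value, warnings)``.
    """
    total = coeffs.b0
    warnings: list[str] = []
    for kind, v in gc.counts.items():
        if v == 0:
            continue
        if kind in coeffs.bk:
            total += v * coeffs.bk[kind]
        else:
            warnings.append(f"no coefficient for group {kind!r} (count {v}); contributed 0")
    return total, warnings


def log10_c_star(
    log10_p: float, molar_mass: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Saturation mass concentration, log10 of ug m^-3.

    ``C* = 1e6 * M * P / (R * T)`` with M in g/mol, P in atm,
    R = 8.20574e-5 m^3 atm / (K mol).
    """
    if not molar_mass > 0:
        raise VolatilityError("molar_mass must be positive")
    if not temperature > 0:
        raise VolatilityError("temperature must be positive")
    return 6.0 + math.log10(molar_mass) + log10_p - math.log10(R_ATM * temperature)


def categorize(log10_cstar: float) -> str:
    """RVI class: nonvolatile (< -2), low (-2..0), intermediate (0..2), high (> 2)."""
    if not math.isfinite(log10_cstar):
        raise VolatilityError("log10 C* must be finite")
    if log10_cstar < -2:
        return "nonvolatile"
    if log10_cstar < 0:
        return "low"
    if log10_cstar <= 2:
        return "intermediate"
    return "high"


def assess_compound(
    compound: CompoundRecord,
    coeffs: SimpolCoefficients | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> VolatilityResult:
    """Full per-compound assessment; structureless records are flagged
    unassessable rather than dropped."""
    if coeffs is None:
        coeffs = load_coefficients()
    if not compound.smiles or compound.molar_mass is None:
        return VolatilityResult(
            compound_id=compound.compound_id,
            group_counts=None, log10_p=None, log10_cstar=None,
            category=None, assessable=False,
            warnings=("no structure or molar mass; unassessable",),
        )
    gc = count_functional_groups(compound.smiles)
    p, warnings = log10_vapor_pressure(gc, coeffs)
    cstar = log10_c_star(p, compound.molar_mass, temperature)
    return VolatilityResult(
        compound_id=compound.compound_id,
        group_counts=gc,
        log10_p=p,
        log10_cstar=cstar,
        category=categorize(cstar),
        warnings=tuple(warnings),
    )


def assess_universe(
    universe,
    coeffs: SimpolCoefficients | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> dict[str, VolatilityResult]:
    """Assess every compound in a universe (id -> result)."""
    if coeffs is None:
        coeffs = load_coefficients()
    return {
        cid: assess_compound(c, coeffs, temperature)
        for cid, c in universe.compounds.items()
    }
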