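"""Functional-group counting, vapor-pressure sums, C* conversion and RVI classes."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from volatilome.synth import (
    NAMED_COMPOUNDS,
    certified_group_counts,
    template_molecules,
)
from volatilome.universe import CompoundRecord
from volatilome.volatility import (
    DEFAULT_TEMPERATURE,
    R_ATM,
    GroupCounts,
    VolatilityError,
    assess_compound,
    categorize,
    count_functional_groups,
    load_coefficients,
    log10_c_star,
    log10_vapor_pressure,
)

COEFFS = load_coefficients()
TEMPLATES = template_molecules()


@pytest.mark.parametrize("name", sorted(TEMPLATES))
def test_group_counter_matches_certified_counts(name):
    t = TEMPLATES[name]
    assert count_functional_groups(t.smiles).counts == \
        certified_group_counts(t).counts


def test_template_library_coverage():
    assert set(NAMED_COMPOUNDS) <= set(TEMPLATES)
    assert len(NAMED_COMPOUNDS) >= 11
    assert len(set(TEMPLATES) - set(NAMED_COMPOUNDS)) >= 20


def test_precedence_formic_acid_is_acid_not_aldehyde():
    gc = count_functional_groups("OC=O")
    assert gc.get("carboxylic_acid") == 1
    assert gc.get("aldehyde") == 0
    assert gc.get("hydroxyl") == 0


def test_selenol_counts_as_unmatched_with_warning_downstream():
    gc = count_functional_groups("C[SeH]")
    assert gc.nonzero() == {"carbon": 1, "unmatched_heteroatom": 1}
    _, warnings = log10_vapor_pressure(gc, COEFFS)
    assert warnings and "unmatched_heteroatom" in warnings[0]


def test_bad_smiles_rejected():
    with pytest.raises(VolatilityError):
        count_functional_groups("not-a-smiles")
    with pytest.raises(VolatilityError):
        count_functional_groups("CCO.CC=O")  # multi-fragment


def test_counter_is_atom_order_invariant():
    for name in ("glucose", "phenylpyruvate", "ethyl acetate", "putrescine"):
        smiles = TEMPLATES[name].smiles
        mol = Chem.MolFromSmiles(smiles)
        perm = list(range(mol.GetNumAtoms()))[::-1]
        renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        assert count_functional_groups(renumbered).counts == \
            count_functional_groups(smiles).counts


def test_zero_groups_return_intercept_exactly():
    gc = GroupCounts(counts={})
    value, warnings = log10_vapor_pressure(gc, COEFFS)
    assert value == COEFFS.b0
    assert warnings == []


def test_vapor_pressure_linear_in_each_group():
    base = {"carbon": 3, "hydroxyl": 1}
    v0, _ = log10_vapor_pressure(GroupCounts(counts=dict(base)), COEFFS)
    for kind, b in COEFFS.bk.items():
        bumped = dict(base)
        bumped[kind] = bumped.get(kind, 0) + 2
        v1, _ = log10_vapor_pressure(GroupCounts(counts=bumped), COEFFS)
        assert v1 - v0 == pytest.approx(2 * b, abs=1e-12)


def test_ethanol_hand_summed_value():
    # b0 + 2*b_carbon + b_hydroxyl = 1.79 - 0.876 - 2.23
    gc = count_functional_groups("CCO")
    value, _ = log10_vapor_pressure(gc, COEFFS)
    assert value == pytest.approx(1.79 + 2 * (-0.438) + (-2.23), abs=1e-12)
    cstar = log10_c_star(value, 46.07)
    by_hand = math.log10(1e6 * 46.07 * 10 ** value / (R_ATM * DEFAULT_TEMPERATURE))
    assert cstar == pytest.approx(by_hand, abs=1e-10)


def test_c_star_unit_identity_and_mass_linearity():
    # construct M so that 1e6 * M * P / (R T) == 1
    p = -3.0
    mass = R_ATM * DEFAULT_TEMPERATURE / (1e6 * 10 ** p)
    assert log10_c_star(p, mass) == pytest.approx(0.0, abs=1e-10)
    assert log10_c_star(p, 2 * mass) - log10_c_star(p, mass) == \
        pytest.approx(math.log10(2), abs=1e-12)
    with pytest.raises(VolatilityError):
        log10_c_star(p, -1.0)
    with pytest.raises(VolatilityError):
        log10_c_star(p, mass, temperature=0.0)


@pytest.mark.parametrize(
    "value,expected",
    [
        (-2.5, "nonvolatile"),
        (-2.0, "low"),
        (-0.5, "low"),
        (0.0, "intermediate"),
        (2.0, "intermediate"),  # "> 2" is strict
        (2.0001, "high"),
        (3.0, "high"),
    ],
)
def test_rvi_category_boundaries(value, expected):
    assert categorize(value) == expected


def test_category_rejects_non_finite():
    with pytest.raises(VolatilityError):
        categorize(float("nan"))


def test_alcohol_series_strictly_decreasing():
    prev_p = prev_c = None
    for n in range(1, 9):
        record = CompoundRecord(f"alc{n}", f"C{n} alcohol", "C" * n + "O",
                                None, 14.03 * n + 18.02)
        res = assess_compound(record, COEFFS)
        if prev_p is not None:
            assert res.log10_p < prev_p
            assert res.log10_cstar < prev_c
        prev_p, prev_c = res.log10_p, res.log10_cstar


def test_assess_ethanol_high_and_polyol_nonvolatile():
    ethanol = CompoundRecord("C1", "ethanol", "CCO", "C2H6O", 46.07)
    assert assess_compound(ethanol, COEFFS).category == "high"
    polyol = TEMPLATES["icosan-icosaol"]
    record = CompoundRecord("C2", polyol.name, polyol.smiles, None, 620.0)
    assert assess_compound(record, COEFFS).category == "nonvolatile"


def test_structureless_record_flagged_unassessable():
    record = CompoundRecord("C3", "mystery", None, "C2H6O", 46.07)
    res = assess_compound(record, COEFFS)
    assert not res.assessable
    assert res.category is None
    assert res.warnings


@settings(derandomize=True, max_examples=50)
@given(
    counts=st.dictionaries(
        st.sampled_from(sorted(COEFFS.bk)), st.integers(0, 10), max_size=6
    ),
    extra=st.sampled_from(sorted(COEFFS.bk)),
)
def test_pressure_sum_is_additive_property(counts, extra):
    """log10 P is linear: adding one group changes the sum by exactly b_k."""
    v0, _ = log10_vapor_pressure(GroupCounts(counts=dict(counts)), COEFFS)
    bumped = dict(counts)
    bumped[extra] = bumped.get(extra, 0) + 1
    v1, _ = log10_vapor_pressure(GroupCounts(counts=bumped), COEFFS)
    assert v1 - v0 == pytest.approx(COEFFS.bk[extra], abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=-30, max_value=30, allow_nan=False))
def test_categorize_is_total_and_monotone_property(x):
    order = ["nonvolatile", "low", "intermediate", "high"]
    cat = categorize(x)
    assert cat in order
    assert order.index(categorize(x + 0.5)) >= order.index(cat)


def test_negative_coefficient_groups_strictly_decrease_pressure():
    base, _ = log10_vapor_pressure(GroupCounts(counts={"carbon": 4}), COEFFS)
    for kind, b in COEFFS.bk.items():
        if kind == "carbon" or b >= 0:
            continue
        with_group, _ = log10_vapor_pressure(
            GroupCounts(counts={"carbon": 4, kind: 1}), COEFFS
        )
        assert with_group < base
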