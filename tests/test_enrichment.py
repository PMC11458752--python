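"""Hypergeometric enrichment and the conservative VOC filter."""

import itertools
import math

import pytest

from volatilome.enrichment import (
    conservative_filter,
    emission_confirmed,
    enriched_pathways,
    funnel_counts,
    hypergeom_upper_tail,
    is_organic,
    pathway_enrichment,
    voc_pathway_support,
)
from volatilome.synth import GeneratorConfig, funnel_universe, generate_universe
from volatilome.translate import common_enzymes, translate_ko_style, translate_swissprot_style
from volatilome.universe import CompoundRecord
from volatilome.volatility import assess_universe


def enumeration_upper_tail(n_universe, n_luca, n_pathway, n_overlap):
    """Oracle: enumerate every n_pathway-subset of the universe and count
    how often it contains at least n_overlap of the first n_luca items."""
    hits = total = 0
    for subset in itertools.combinations(range(n_universe), n_pathway):
        total += 1
        if sum(1 for i in subset if i < n_luca) >= n_overlap:
            hits += 1
    return hits / total


def test_hypergeometric_matches_enumeration_on_small_grid():
    for n in (5, 8, 10):
        for k_luca in range(n + 1):
            for n_path in range(n + 1):
                for overlap in range(min(k_luca, n_path) + 1):
                    expected = enumeration_upper_tail(n, k_luca, n_path, overlap)
                    got = hypergeom_upper_tail(n, k_luca, n_path, overlap)
                    assert got == pytest.approx(expected, abs=1e-12)


def test_worked_example_five_over_210():
    assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)
    assert enumeration_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-15)


def test_zero_overlap_and_degenerate_cases():
    assert hypergeom_upper_tail(10, 5, 4, 0) == 1.0
    # ancestral set == whole universe: every pathway fully overlaps
    assert hypergeom_upper_tail(10, 10, 4, 4) == pytest.approx(1.0, abs=1e-12)


def test_pmf_sums_to_one():
    from scipy.stats import hypergeom

    for n, k, m in [(12, 5, 7), (30, 10, 4), (100, 40, 25)]:
        lo = max(0, k + m - n)
        hi = min(k, m)
        total = sum(hypergeom.pmf(i, n, k, m) for i in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_p_non_increasing_in_overlap():
    prev = None
    for overlap in range(0, 6):
        p = hypergeom_upper_tail(40, 10, 6, overlap)
        if prev is not None:
            assert p <= prev + 1e-15
        prev = p


def test_is_organic_rules():
    water = CompoundRecord("W", "water", "O", "H2O", 18.02)
    co2 = CompoundRecord("D", "carbon dioxide", "O=C=O", "CO2", 44.01)
    ethanol = CompoundRecord("E", "ethanol", "CCO", "C2H6O", 46.07)
    cyanide = CompoundRecord("N", "hydrogen cyanide", "C#N", "CHN", 27.03)
    formula_only = CompoundRecord("F", "by formula", None, "C3H8", 44.1)
    nothing = CompoundRecord("X", "unknown", None, None, None)
    assert not is_organic(water)
    assert not is_organic(co2)
    assert not is_organic(cyanide)
    assert is_organic(ethanol)
    assert is_organic(formula_only)
    with pytest.raises(ValueError):
        is_organic(nothing)


@pytest.fixture(scope="module")
def run_context():
    uni, truth = generate_universe(GeneratorConfig(seed=0))
    cogs = set(uni.cogs)
    common = common_enzymes(
        translate_swissprot_style(cogs, uni), translate_ko_style(cogs, uni), uni
    )
    vol = assess_universe(uni)
    enr = pathway_enrichment(common.ec_set, uni)
    return uni, truth, common, vol, enr


def test_planted_pathways_are_the_enriched_set(run_context):
    uni, truth, common, vol, enr = run_context
    assert enriched_pathways(enr) == set(truth.enriched_pathways)


def test_voc_pathway_support_cases(run_context):
    uni, truth, common, vol, enr = run_context
    enriched = enriched_pathways(enr)
    luca = common.ec_set
    voc = next(iter(truth.true_vocs))
    ok, pairs = voc_pathway_support(voc, luca, enriched, uni)
    assert ok and pairs
    for ec, pid in pairs:
        assert pid in enriched and ec in uni.pathways[pid].ec_numbers
    # the putrescine-style decoy is linked only outside enriched pathways
    decoy = truth.decoys["non_enriched_pathway"]
    assert voc_pathway_support(decoy, luca, enriched, uni)[0] is False
    # a compound with no ancestral link at all
    assert voc_pathway_support("C99999", luca, enriched, uni)[0] is False


def test_emission_lookup(run_context):
    uni, truth, *_ = run_context
    confirmed_voc = next(iter(truth.true_vocs))
    assert emission_confirmed(confirmed_voc, uni)
    assert not emission_confirmed(truth.decoys["no_emission"], uni)
    assert not emission_confirmed("C-absent", uni)


def test_each_decoy_fails_exactly_one_criterion(run_context):
    uni, truth, common, vol, enr = run_context
    traces, final, _ = conservative_filter(common, vol, enr, uni)
    by_id = {t.compound_id: t for t in traces}
    expectations = {
        "inorganic": "is_organic",
        "low_volatility": "is_high_volatility",
        "no_emission": "emission_confirmed",
        "non_enriched_pathway": "in_enriched_pathway_with_luca_enzyme",
    }
    for kind, failing_flag in expectations.items():
        trace = by_id[truth.decoys[kind]]
        assert not trace.final
        assert getattr(trace, failing_flag) is False
        others = {
            "is_organic", "is_high_volatility", "emission_confirmed",
            "in_enriched_pathway_with_luca_enzyme",
        } - {failing_flag}
        for flag in others:
            assert getattr(trace, flag) is True, (kind, flag)
        if kind != "few_studies":
            assert trace.study_support_count >= 4
    few = by_id[truth.decoys["few_studies"]]
    assert not few.final and few.study_support_count < 4
    assert all(f is True for f in few.flags())


def test_filter_funnel_is_monotone_and_final_nested(run_context):
    uni, truth, common, vol, enr = run_context
    traces, final, funnel = conservative_filter(common, vol, enr, uni)
    values = list(funnel.values())
    assert values == sorted(values, reverse=True)
    organic = {t.compound_id for t in traces if t.is_organic}
    emitted = {t.compound_id for t in traces if t.is_organic and t.is_high_volatility
               and t.emission_confirmed}
    assert set(final) <= emitted <= organic <= common.compounds


def test_relaxing_alpha_never_shrinks_final_list(run_context):
    uni, truth, common, vol, enr = run_context
    _, strict, _ = conservative_filter(common, vol, enr, uni, alpha=0.01)
    _, loose, _ = conservative_filter(common, vol, enr, uni, alpha=0.2)
    assert set(strict) <= set(loose)


def test_funnel_fixture_reproduces_prescribed_counts():
    uni, common = funnel_universe()
    vol = assess_universe(uni)
    enr = pathway_enrichment(common.ec_set, uni)
    _, final, funnel = conservative_filter(common, vol, enr, uni)
    assert funnel["common"] == 206
    assert funnel["organic"] == 186
    assert funnel["emission_confirmed"] == 27
    assert funnel["enriched_supported"] == 9
    assert funnel["final"] == 7 == len(final)


def test_missing_volatility_result_is_an_error(run_context):
    uni, truth, common, vol, enr = run_context
    partial = dict(vol)
    partial.pop(next(iter(common.compounds)))
    with pytest.raises(ValueError, match="missing volatility"):
        conservative_filter(common, partial, enr, uni)
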