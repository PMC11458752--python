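"""Volatilome class profiles and the rank-sum comparison machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from volatilome.profiles import (
    VolatilomeProfile,
    approx_ranksum_p,
    classify,
    compare_profiles,
    exact_ranksum_p,
    genome_volatilome,
    study_volatilome,
)
from volatilome.synth import GeneratorConfig, generate_universe
from volatilome.volatility import assess_universe


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled values
    to the first group and count rank sums at least as extreme."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed", range(6))
def test_exact_ranksum_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
    # integer draws force ties, exercising the midrank handling
    x = rng.integers(0, 5, size=n1).astype(float)
    y = rng.integers(0, 5, size=n2).astype(float)
    assert exact_ranksum_p(x, y) == pytest.approx(brute_force_ranksum_p(x, y),
                                                  abs=1e-12)


def test_identical_samples_give_p_one():
    x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
    assert exact_ranksum_p(x, list(x)) == 1.0
    assert approx_ranksum_p(x, list(x)) == pytest.approx(1.0, abs=0.05)


def test_complete_separation_gives_exact_tail():
    x = list(range(8))
    y = list(range(100, 108))
    # only the two all-low / all-high assignments are as extreme
    assert exact_ranksum_p(x, y) == pytest.approx(2 / math.comb(16, 8), abs=1e-15)


def test_zero_side_versus_positive_side_is_significant():
    zeros = [0.0] * 8
    pos = [5.0, 6.0, 7.0, 8.0, 5.5, 6.5, 7.5, 8.5]
    assert exact_ranksum_p(zeros, pos) < 0.01


def test_exact_and_approximate_agree_at_moderate_n():
    rng = np.random.default_rng(123)
    for _ in range(20):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert abs(exact_ranksum_p(x, y) - approx_ranksum_p(x, y)) < 0.01


def test_all_constant_data_gives_p_one_with_warning(caplog):
    assert approx_ranksum_p([2.0] * 5, [2.0] * 6) == 1.0


@pytest.fixture(scope="module")
def profiled_universe():
    uni, truth = generate_universe(GeneratorConfig(seed=3))
    vol = assess_universe(uni)
    return uni, truth, vol


def test_classify_lookup_and_sentinel(profiled_universe):
    uni, _, _ = profiled_universe
    known = next(iter(uni.chem_taxonomy))
    result = classify([known, "C-unknown"], uni)
    assert result[known] == uni.chem_taxonomy[known]
    assert result["C-unknown"].subclass == "unclassified"


def test_genome_profile_percentages_sum_to_100(profiled_universe):
    uni, _, vol = profiled_universe
    nonempty = 0
    for genome in uni.genomes.values():
        profile = genome_volatilome(genome, uni, vol)
        if profile.empty:
            continue
        nonempty += 1
        assert sum(profile.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in profile.percentages.values())
    assert nonempty >= 2


def test_empty_genome_profile_flagged(profiled_universe):
    uni, _, vol = profiled_universe
    from volatilome.universe import Genome

    empty = Genome("G-empty", "Bacteria", "b-phy-1", frozenset())
    assert genome_volatilome(empty, uni, vol).empty


def test_study_profiles_from_shared_compounds_are_identical():
    table = pd.DataFrame(
        {
            "compound_id": ["C1", "C2"],
            "method": ["common"] * 2,
            "studies": ["Weiss;Wang", "Weiss;Wang"],
            "n_studies": [2, 2],
            "ecs": ["1.1.1.1", "2.2.2.2"],
        }
    )
    uni, _, vol = generate_universe(GeneratorConfig(seed=3)), None, None
    # reuse a real universe for taxonomy/volatility context
    uni, truth = uni
    vol = assess_universe(uni)
    p1 = study_volatilome("Weiss", table, uni, vol)
    p2 = study_volatilome("Wang", table, uni, vol)
    assert p1.percentages == p2.percentages


def test_profile_permutation_invariance(profiled_universe):
    uni, _, vol = profiled_universe
    from volatilome.profiles import _profile_from_compounds

    ids = list(uni.compounds)[:40]
    p1 = _profile_from_compounds("x", set(ids), uni, vol)
    p2 = _profile_from_compounds("x", set(reversed(ids)), uni, vol)
    assert p1.percentages == p2.percentages


def test_compare_profiles_pooled_and_per_domain(profiled_universe):
    uni, _, vol = profiled_universe
    from volatilome.pipeline import run_all

    report = run_all(uni)
    rows = report.profile_comparison
    assert rows, "expected at least one compared subclass"
    for row in rows:
        assert 0.0 <= row["p_value"] <= 1.0


def test_compare_profiles_requires_two_per_side():
    lone = VolatilomeProfile("a", {"x": 100.0}, 1)
    with pytest.raises(ValueError):
        compare_profiles([lone], [lone, lone])


def test_bh_correction_is_monotone():
    profiles_a = [VolatilomeProfile(f"s{i}", {"x": 10.0 + i, "y": 90.0 - i}, 5)
                  for i in range(4)]
    profiles_b = [VolatilomeProfile(f"g{i}", {"x": 60.0 + i, "y": 40.0 - i}, 5)
                  for i in range(4)]
    df = compare_profiles(profiles_a, profiles_b, bh_correct=True)
    assert (df["p_adjusted"] >= df["p_value"] - 1e-12).all()
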