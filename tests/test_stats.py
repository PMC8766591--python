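"""Error summaries and the Jonckheere-Terpstra trend test vs independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fascore.stats import (
    RankedGrowth,
    StatisticsError,
    error_summary,
    groups_from_ranked,
    jonckheere_terpstra,
    jt_from_table,
)


def brute_force_jt(groups):
    """Independent O(n^2) pairwise counter."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if a < b:
                        jt += 1.0
                    elif a == b:
                        jt += 0.5
    return jt


def enumeration_p(groups, jt_obs):
    """Exhaustive-permutation oracle: fraction of distinct label arrangements
    with JT >= observed, enumerated directly from label permutations."""
    pooled = [x for g in groups for x in g]
    labels = [i for i, g in enumerate(groups) for _ in g]
    seen = set(itertools.permutations(labels))
    hits = total = 0
    for perm in seen:
        regrouped = [[] for _ in groups]
        for lab, x in zip(perm, pooled):
            regrouped[lab].append(x)
        total += 1
        if brute_force_jt(regrouped) >= jt_obs - 1e-9:
            hits += 1
    return hits / total


# --- error summary ---------------------------------------------------------

def test_error_summary_zero_rates():
    assert error_summary([0.0, 0.0, 0.0]) == (0.0, 0.0, 3)


def test_error_summary_hand_computed():
    mean, sd, n = error_summary([0.1, -0.1])
    assert mean == pytest.approx(0.0)
    assert sd == pytest.approx(math.sqrt(2) * 0.1)  # sample sd, n-1 denominator
    assert n == 2


def test_error_summary_single_value_has_undefined_sd():
    mean, sd, n = error_summary([0.25])
    assert mean == 0.25 and n == 1 and math.isnan(sd)


def test_error_summary_empty_rejected():
    with pytest.raises(StatisticsError):
        error_summary([])


# --- JT statistic ----------------------------------------------------------

def test_two_by_two_increasing_is_exact_sixth():
    res = jonckheere_terpstra([[1, 2], [3, 4]])
    assert res.statistic == 4.0
    assert res.pvalue == pytest.approx(1 / 6)
    assert res.method == "exact"


def test_degenerate_all_ties():
    res = jonckheere_terpstra([[5, 5], [5, 5], [5, 5]])
    assert res.statistic == res.null_mean
    assert res.pvalue == pytest.approx(1.0)


@given(seed=st.integers(0, 10_000))
def test_statistic_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 5)
    groups = [rng.integers(0, 8, size=rng.integers(1, 6)).tolist() for _ in range(k)]
    res = jonckheere_terpstra(groups, method="normal")
    assert res.statistic == brute_force_jt(groups)


@pytest.mark.parametrize("sizes", [(2, 2), (3, 3), (2, 3, 2), (3, 2, 3), (1, 4, 2)])
def test_exact_p_matches_enumeration_oracle_continuous(sizes):
    rng = np.random.default_rng(sum(sizes))
    groups = [list(rng.normal(i * 0.5, 1.0, size=s)) for i, s in enumerate(sizes)]
    res = jonckheere_terpstra(groups, method="exact")
    oracle = enumeration_p(groups, res.statistic)
    assert res.pvalue == pytest.approx(oracle, abs=1e-12)


@pytest.mark.parametrize("sizes", [(2, 2), (3, 2, 2), (2, 2, 2)])
def test_exact_p_matches_enumeration_oracle_with_ties(sizes):
    rng = np.random.default_rng(17)
    groups = [list(rng.integers(0, 3, size=s).astype(float)) for s in sizes]
    res = jonckheere_terpstra(groups, method="exact")
    oracle = enumeration_p(groups, res.statistic)
    assert res.pvalue == pytest.approx(oracle, abs=1e-12)


def test_reversal_maps_jt_to_complement():
    rng = np.random.default_rng(3)
    groups = [list(rng.permutation(20)[:4] + 100 * i) for i in range(3)]  # no ties
    fwd = jonckheere_terpstra(groups, method="normal").statistic
    rev = jonckheere_terpstra(list(reversed(groups)), method="normal").statistic
    total_cross = sum(
        len(groups[i]) * len(groups[j])
        for i in range(3) for j in range(i + 1, 3)
    )
    assert fwd + rev == total_cross


def test_decreasing_alternative_mirrors_increasing():
    groups = [[5.0, 6.0], [3.0, 4.0], [1.0, 2.0]]
    inc = jonckheere_terpstra(groups, alternative="increasing")
    dec = jonckheere_terpstra(groups, alternative="decreasing")
    assert dec.pvalue < 0.1 < inc.pvalue


def test_normal_approximation_converges_to_exact():
    # pooled n = 9 and 12: the continuity-corrected approximation agrees with
    # the exact p within 0.02; the uncorrected error shrinks as n grows
    mean_cc, mean_plain = {}, {}
    for n_per_group in (3, 4):
        rng = np.random.default_rng(5)
        cc_diffs, plain_diffs = [], []
        for _ in range(10):
            groups = [list(rng.normal(0.3 * i, 1.0, size=n_per_group))
                      for i in range(3)]
            exact = jonckheere_terpstra(groups, method="exact").pvalue
            cc = jonckheere_terpstra(groups, method="normal",
                                     continuity_correction=True).pvalue
            plain = jonckheere_terpstra(groups, method="normal").pvalue
            cc_diffs.append(abs(exact - cc))
            plain_diffs.append(abs(exact - plain))
        mean_cc[n_per_group] = np.mean(cc_diffs)
        mean_plain[n_per_group] = np.mean(plain_diffs)
    assert mean_cc[3] <= 0.02 and mean_cc[4] <= 0.02
    assert mean_plain[4] < mean_plain[3]  # convergence with growing n


def test_single_or_empty_group_rejected():
    with pytest.raises(StatisticsError):
        jonckheere_terpstra([[1, 2, 3]])
    with pytest.raises(StatisticsError):
        jonckheere_terpstra([[1.0], []])


def test_ranked_growth_validation_and_grouping():
    with pytest.raises(StatisticsError):
        RankedGrowth(0.1, rank=4)
    ranked = [RankedGrowth(0.1, 1), RankedGrowth(0.3, 2), RankedGrowth(0.5, 3),
              RankedGrowth(0.0, 1)]
    groups = groups_from_ranked(ranked)
    assert groups == [[0.1, 0.0], [0.3], [0.5]]


def test_jt_from_table_surface():
    import pandas as pd

    df = pd.DataFrame({
        "pair_id": list("abcdef"),
        "growth_rate": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
        "rank": [1, 1, 2, 2, 3, 3],
    })
    out = jt_from_table(df)
    assert out["group_ns"] == [2, 2, 2]
    assert out["JT"] == brute_force_jt([[0.0, 0.1], [0.2, 0.3], [0.4, 0.5]])
    assert 0.0 < out["p"] < 0.1
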