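"""Protein-level direction consistency, the 80% rule, and the resampling null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helix_ieg.ieg_calling import (call_iegs, contig_directions,
                                   permute_contig_fraction,
                                   permute_protein_consistency,
                                   protein_consistency)


def oracle_direction_both(a, b):
    if np.isnan(a) or np.isnan(b):
        return "none"
    if a > 0 and b > 0:
        return "up"
    if a < 0 and b < 0:
        return "down"
    return "none"


def oracle_direction_either(a, b):
    pos = sum(v > 0 for v in (a, b) if not np.isnan(v))
    neg = sum(v < 0 for v in (a, b) if not np.isnan(v))
    if pos >= 1 and neg == 0:
        return "up"
    if neg >= 1 and pos == 0:
        return "down"
    return "none"


def test_direction_examples():
    lf = {"E1": pd.Series([1.2, 1.2]), "E2": pd.Series([0.3, -0.3])}
    both = contig_directions(lf, "both")
    assert both.tolist() == ["up", "none"]
    either = contig_directions(lf, "either")
    assert either.tolist() == ["up", "none"]   # conflicting signs stay none


def test_direction_matches_truth_table_oracle(rng):
    vals = rng.choice([1.5, -0.7, 0.0, np.nan], size=(200, 2))
    lf = {"E1": pd.Series(vals[:, 0]), "E2": pd.Series(vals[:, 1])}
    both = contig_directions(lf, "both")
    either = contig_directions(lf, "either")
    for i in range(200):
        assert both.iloc[i] == oracle_direction_both(*vals[i])
        assert either.iloc[i] == oracle_direction_either(*vals[i])


def test_eighty_percent_rule_inclusive():
    directions = pd.Series(["up"] * 4 + ["down"] + ["up"] * 3 + ["down"],
                           index=[f"c{i}" for i in range(9)])
    groups = {"p_pass": [f"c{i}" for i in range(5)],     # 4/5 = 80% -> passes
              "p_fail": [f"c{i}" for i in range(5, 9)]}  # 3/4 = 75% -> fails
    table = protein_consistency(groups, directions)
    assert bool(table.loc["p_pass", "passes_80"]) is True
    assert bool(table.loc["p_fail", "passes_80"]) is False
    assert table.loc["p_pass", "frac_up"] == pytest.approx(0.8)


def test_fractions_over_all_mapped_contigs():
    # direction 'none' contigs count in the denominator only
    directions = pd.Series(["up", "up", "none", "none"],
                           index=["a", "b", "c", "d"])
    table = protein_consistency({"p": ["a", "b", "c", "d"]}, directions)
    assert table.loc["p", "frac_up"] == pytest.approx(0.5)
    assert table.loc["p", "frac_up"] + table.loc["p", "frac_down"] <= 1


def test_passes_80_monotone_under_aligned_addition(rng):
    """Adding an aligned-direction contig never flips pass -> fail."""
    for _ in range(30):
        n = int(rng.integers(1, 10))
        dirs = list(rng.choice(["up", "down", "none"], size=n))
        idx = [f"c{i}" for i in range(n + 1)]
        before = protein_consistency(
            {"p": idx[:n]}, pd.Series(dirs + ["x"], index=idx).iloc[:n])
        grown = protein_consistency(
            {"p": idx}, pd.Series(dirs + ["up"], index=idx))
        if bool(before.loc["p", "passes_80_up"]):
            assert bool(grown.loc["p", "passes_80_up"])


def test_permutation_nothing_to_beat_gives_p_one():
    directions = pd.Series(["none"] * 6, index=[f"c{i}" for i in range(6)])
    pool = pd.Series(["up"] * 20 + ["down"] * 20,
                     index=[f"e{i}" for i in range(40)])
    res = permute_protein_consistency({"p": list(directions.index)},
                                      directions, pool, n_permutations=99,
                                      seed=0)
    assert res.observed == 0.0
    assert res.p_value == 1.0


def test_permutation_deterministic_and_floor():
    directions = pd.Series(["up"] * 5, index=[f"c{i}" for i in range(5)])
    pool = pd.Series(["up"] * 5 + ["down"] * 45,
                     index=[f"e{i}" for i in range(50)])
    groups = {"p": list(directions.index)}
    r1 = permute_protein_consistency(groups, directions, pool,
                                     n_permutations=200, seed=7)
    r2 = permute_protein_consistency(groups, directions, pool,
                                     n_permutations=200, seed=7)
    assert r1.p_value == r2.p_value
    assert np.array_equal(r1.null, r2.null)
    assert r1.p_value >= 1 / 201          # (r+1)/(B+1) floor


def test_permutation_pool_must_cover_largest_protein():
    directions = pd.Series(["up"] * 6, index=[f"c{i}" for i in range(6)])
    pool = pd.Series(["up"] * 3, index=["e0", "e1", "e2"])
    with pytest.raises(ValueError):
        permute_protein_consistency({"p": list(directions.index)},
                                    directions, pool, n_permutations=10, seed=0)


def test_planted_consistency_significant_and_scrambled_not(rng):
    """Planted direction-consistent proteins beat a balanced resampling null;
    scrambling the directions collapses the signal."""
    n_prot, per = 25, 4
    contigs = [f"c{i}" for i in range(n_prot * per)]
    groups = {f"p{k}": contigs[k * per:(k + 1) * per] for k in range(n_prot)}
    planted = pd.Series(["up"] * (n_prot * per), index=contigs)
    pool_idx = [f"e{i}" for i in range(400)]
    pool = pd.Series(rng.permutation(["up"] * 200 + ["down"] * 200),
                     index=pool_idx)
    res = permute_protein_consistency(groups, planted, pool,
                                      n_permutations=500, seed=3)
    assert res.observed == 100.0
    assert res.p_value <= 0.01
    scrambled = pd.Series(rng.choice(["up", "down"], size=len(contigs)),
                          index=contigs)
    res2 = permute_protein_consistency(groups, scrambled, pool,
                                       n_permutations=500, seed=3)
    assert res2.p_value > 0.05


def test_contig_fraction_null_p_uniform(rng):
    """Under a null where the observed set is itself a draw from the pool,
    the permutation p-value is approximately uniform (KS check)."""
    pool = pd.Series(rng.choice(["up", "down"], size=300),
                     index=[f"e{i}" for i in range(300)])
    pvals = []
    for rep in range(200):
        draw = rng.choice((pool == "up").to_numpy(), size=30, replace=False)
        res = permute_contig_fraction(30, float(draw.mean()), pool,
                                      n_permutations=200, seed=rep)
        pvals.append(res.p_value)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.001


def test_call_iegs_candidate_rules():
    directions = pd.Series(["up", "up", "up", "up", "down"],
                           index=["a", "b", "c", "d", "e"])
    de_flags = pd.Series([True, False, False, True, False],
                         index=["a", "b", "c", "d", "e"])
    groups = {"p_cand": ["a", "b", "c"],   # 1 DE + 2 non-DE, all up
              "p_half": ["d", "e"]}        # 1 DE up + 1 non-DE down -> 50%
    calls = call_iegs(groups, directions, de_flags)
    assert bool(calls.loc["p_cand", "candidate_ieg"]) is True
    assert bool(calls.loc["p_half", "candidate_ieg"]) is False
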