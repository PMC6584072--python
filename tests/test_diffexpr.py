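"""Dispersion estimation, the conditional exact NB test, BH-FDR, DE gates,
overlap and direction-concordance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helix_ieg import diffexpr as de
from helix_ieg import synthetic_data as synth


def _pseudo(x):
    df = pd.DataFrame(x, columns=[f"s{j}" for j in range(x.shape[1])])
    groups = pd.Series(["A"] * (x.shape[1] // 2) + ["B"] * (x.shape[1] - x.shape[1] // 2),
                       index=df.columns)
    return df, groups


def test_dispersion_poisson_counts_near_zero(rng):
    mu = rng.uniform(20, 200, size=3000)
    x = rng.poisson(mu[:, None], size=(3000, 12)).astype(float)
    df, groups = _pseudo(x)
    model = de.estimate_dispersion(df, groups)
    assert model.common < 0.01
    assert model.per_contig.median() < 0.05


def test_dispersion_recovers_planted_phi(rng):
    phi = 0.2
    mu = rng.uniform(20, 200, size=5000)
    r = 1 / phi
    x = rng.negative_binomial(r, r / (r + mu[:, None]), size=(5000, 12)).astype(float)
    df, groups = _pseudo(x)
    model = de.estimate_dispersion(df, groups)
    assert model.common == pytest.approx(phi, rel=0.20)


def test_dispersion_constant_contig_is_zero():
    x = np.vstack([np.full(8, 50.0), np.arange(8, dtype=float) * 10 + 5])
    df, groups = _pseudo(x)
    model = de.estimate_dispersion(df, groups)
    assert model.per_contig.iloc[0] == 0.0


def test_exact_test_binomial_limit():
    """One sample per group, phi=0, counts (0 | 10): every split of the total
    is equally likely, so p = 2 * (1/2)^10."""
    a = pd.DataFrame({"a1": [0]})
    b = pd.DataFrame({"b1": [10]})
    eff = pd.Series([100.0, 100.0], index=["a1", "b1"])
    p = de.exact_test(a, b, 0.0, eff)
    assert p.iloc[0] == pytest.approx(2 / 1024)


def test_exact_test_symmetric_extreme_and_swap(rng):
    a = pd.DataFrame(rng.integers(10, 100, size=(5, 3)),
                     columns=["a1", "a2", "a3"])
    b = pd.DataFrame(rng.integers(10, 100, size=(5, 3)),
                     columns=["b1", "b2", "b3"])
    eff = pd.Series(1000.0, index=list(a.columns) + list(b.columns))
    p_ab = de.exact_test(a, b, 0.1, eff)
    p_ba = de.exact_test(b, a, 0.1, eff)
    assert np.allclose(p_ab, p_ba)  # symmetric under group swap
    # identical group sums -> p = 1
    a1 = pd.DataFrame({"a1": [25]}); b1 = pd.DataFrame({"b1": [25]})
    eff1 = pd.Series([500.0, 500.0], index=["a1", "b1"])
    assert de.exact_test(a1, b1, 0.2, eff1).iloc[0] == pytest.approx(1.0)


def test_exact_test_monotone_in_imbalance():
    eff = pd.Series([1000.0, 1000.0], index=["a1", "b1"])
    total = 60
    pvals = []
    for a_count in (30, 35, 40, 45, 50, 55):
        a = pd.DataFrame({"a1": [a_count]})
        b = pd.DataFrame({"b1": [total - a_count]})
        pvals.append(de.exact_test(a, b, 0.1, eff).iloc[0])
    assert all(x >= y for x, y in zip(pvals, pvals[1:]))


def test_exact_test_null_calibration(rng):
    """Type-I error of the exact NB test at the true dispersion is close to
    nominal on null NB counts."""
    phi, n = 0.1, 4000
    mu = rng.uniform(30, 150, size=n)
    r = 1 / phi
    x = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 12))
    a = pd.DataFrame(x[:, :6], columns=[f"a{j}" for j in range(6)])
    b = pd.DataFrame(x[:, 6:], columns=[f"b{j}" for j in range(6)])
    eff = pd.Series(1.0, index=list(a.columns) + list(b.columns))
    p = de.exact_test(a, b, phi, eff)
    rate = (p < 0.05).mean()
    ci = 2.81 * np.sqrt(0.05 * 0.95 / n)   # ~99.5% binomial band
    assert abs(rate - 0.05) < ci + 0.005   # small slack for discreteness


def test_bh_fdr_step_up():
    assert np.allclose(de.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert de.bh_fdr([0.42]) == pytest.approx([0.42])


def brute_force_bh(p):
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        adj[i] = prev
    return np.minimum(adj, 1.0)


def test_bh_fdr_matches_textbook_oracle(rng):
    p = rng.uniform(size=37)
    assert np.allclose(de.bh_fdr(p), brute_force_bh(p))
    # pointwise >= raw p; order-preserving on the sorted scale
    q = de.bh_fdr(p)
    assert (q >= p).all()
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)


def test_bh_fdr_rejects_invalid():
    with pytest.raises(ValueError):
        de.bh_fdr([0.5, 1.2])


def test_call_de_gates():
    t = pd.DataFrame({
        "logFC": [2.0, 0.9, 1.5, -1.4],
        "p": [1e-4, 1e-4, 1e-3, 1e-4],
        "fdr": [0.05, 0.01, 0.001, 0.002],
    })
    out = de.call_de(t)
    # FDR exactly 0.05 is not DE (strict <); |logFC| 0.9 is fold change < 2
    assert out["is_de"].tolist() == [False, False, True, True]
    assert out["direction"].tolist() == ["none", "none", "up", "down"]


def test_overlap_hypergeom_small_enumeration():
    # N=10, K=5, n=4, overlap=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
    p = de.overlap_hypergeom({f"x{i}" for i in range(5)},
                             {"x0", "x1", "x2", "x3"}, 10)
    assert p == pytest.approx(5 / 210)
    assert de.overlap_hypergeom({"a"}, {"b"}, 10) == pytest.approx(1.0)


def test_overlap_hypergeom_study_scale():
    """At the study's reported scale (two DE sets of 350 and 98 among hundreds
    of thousands of expressed contigs, overlap 26) the overlap is wildly
    non-random under either background."""
    a = {f"c{i}" for i in range(350)}
    b = {f"c{i}" for i in range(26)} | {f"d{i}" for i in range(72)}
    assert de.overlap_hypergeom(a, b, 404_678) < 1e-4
    assert de.overlap_hypergeom(a, b, 332_423) < 1e-4


def test_direction_concordance_all_up():
    lf1 = pd.Series([1.0, 2.0, 0.5], index=list("abc"))
    lf2 = pd.Series([0.3, 1.0, 2.0], index=list("abc"))
    r = de.direction_concordance(lf1, lf2, ["a", "b", "c"])
    assert r["frac_up_both"] == 1.0


def test_direction_concordance_chi2_formula():
    counts = {"pp": 30, "pn": 5, "np": 4, "nn": 11}
    idx = []
    s1, s2 = [], []
    k = 0
    for key, n in counts.items():
        for _ in range(n):
            idx.append(f"c{k}"); k += 1
            s1.append(1.0 if key[0] == "p" else -1.0)
            s2.append(1.0 if key[1] == "p" else -1.0)
    lf1 = pd.Series(s1, index=idx)
    lf2 = pd.Series(s2, index=idx)
    r = de.direction_concordance(lf1, lf2, idx)
    chi2, p, _, _ = stats.chi2_contingency([[30, 5], [4, 11]], correction=False)
    assert r["chi2"] == pytest.approx(chi2)
    assert r["chi2_p"] == pytest.approx(p)


def test_de_table_recovers_planted_effects():
    """Planted 3x contigs are called DE with controlled empirical FDR.

    Power is assessed on informatively expressed contigs (mean counts of
    roughly 15+ per sample); at a handful of counts per sample no exact test
    can separate a 3x change from noise with six replicates.
    """
    params = synth.SimParams(n_proteins=300, frac_ieg=0.25, effect_fc=3.0,
                             contigs_per_protein=(1, 2), n_orphan_contigs=0,
                             base_mean_log_range=(1.0, 2.0),
                             dispersion=0.1, individual_sd=0.0, seed=21)
    cm, design, truth = synth.simulate_counts(params)
    table = de.de_table(cm, design, "E1")
    is_ieg = pd.Series(truth.contig_is_ieg).reindex(table.index)
    called = table["is_de"]
    sensitivity = (called & is_ieg).sum() / is_ieg.sum()
    fdr = (called & ~is_ieg).sum() / max(int(called.sum()), 1)
    assert sensitivity >= 0.8
    assert fdr <= 0.10
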