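"""Differential expression between activated and control samples.

The caller is a negative-binomial conditional exact test in the style of
edgeR's classic exact test: counts are rescaled to a common (geometric-mean)
effective library size, a common dispersion is estimated from within-group
Pearson residuals, per-contig method-of-moments dispersions are shrunk toward
it with a fixed weight, and the two-sided p-value sums the probabilities of
all splits of a contig's total between the two groups that are no more likely
than the observed split.  Bit-exact edgeR replication (qCML dispersion,
quantile adjustment) is deliberately not attempted; the caller is validated
by type-I calibration and planted-effect recovery instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from helix_ieg.containers import CountMatrix, samples_for
from helix_ieg.expression import tmm_factors

#: Shrinkage weight on the common dispersion when forming per-contig values.
COMMON_WEIGHT = 0.85


@dataclass
class DispersionModel:
    """Common and per-contig NB dispersions (Var = mu + phi mu^2)."""

    common: float
    per_contig: pd.Series          # method-of-moments, floored at 0
    common_weight: float = COMMON_WEIGHT

    @property
    def shrunk(self) -> pd.Series:
        return self.common_weight * self.common + (1 - self.common_weight) * self.per_contig


def equalize_counts(counts: pd.DataFrame, effective_lib_sizes: pd.Series
                    ) -> pd.DataFrame:
    """Pseudo-counts rescaled to the geometric mean effective library size."""
    eff = effective_lib_sizes.reindex(counts.columns).astype(float)
    common = np.exp(np.mean(np.log(eff)))
    return counts * (common / eff)


def estimate_dispersion(pseudo: pd.DataFrame, groups: pd.Series
                        ) -> DispersionModel:
    """Estimate NB dispersion from library-size-equalized pseudo-counts.

    The common dispersion solves the Pearson moment equation
    ``sum_gs (x - mu_hat)^2 / (mu_hat + phi mu_hat^2) = sum_g (n_g - n_groups)``
    with per-group means fitted per contig.  Per-contig values come from a
    method-of-moments estimate on within-group residuals, floored at 0.
    """
    groups = groups.reindex(pseudo.columns)
    labels = groups.unique()
    if len(labels) < 2 or any((groups == g).sum() < 2 for g in labels):
        # single-sample group: only the common dispersion is meaningful
        import warnings
        warnings.warn("a group has <2 samples; per-contig dispersions set to common")
    x = pseudo.to_numpy(dtype=float)
    resid2 = np.zeros_like(x)
    mu = np.zeros_like(x)
    df_total = 0
    ss_num = np.zeros(x.shape[0])      # MoM numerator per contig
    ss_den = np.zeros(x.shape[0])
    for g in labels:
        cols = np.asarray(groups == g)
        n_g = cols.sum()
        if n_g == 0:
            continue
        m = x[:, cols].mean(axis=1, keepdims=True)
        mu[:, cols] = m
        r2 = (x[:, cols] - m) ** 2
        resid2[:, cols] = r2
        if n_g >= 2:
            df_total += x.shape[0] * (n_g - 1)
            # E[sum (x-mean)^2] = (n-1) * (mu + phi mu^2)
            ss_num += r2.sum(axis=1) - (n_g - 1) * m[:, 0]
            ss_den += (n_g - 1) * m[:, 0] ** 2
    usable = mu > 0

    def pearson_gap(phi: float) -> float:
        v = mu + phi * mu ** 2
        return float(np.sum(resid2[usable] / v[usable]) - df_total)

    if df_total == 0 or pearson_gap(0.0) <= 0:
        common = 0.0
    else:
        hi = 0.1
        while pearson_gap(hi) > 0 and hi < 1e4:
            hi *= 4
        common = float(optimize.brentq(pearson_gap, 0.0, hi))

    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(ss_den > 0, ss_num / ss_den, 0.0)
    per_contig = pd.Series(np.maximum(mom, 0.0), index=pseudo.index)
    return DispersionModel(common=common, per_contig=per_contig)


def _exact_nb_pvalue(a: float, b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact NB p-value for group totals (a | b).

    Conditions on t = a + b; group totals are NB with means proportional to
    group sizes and sizes ``n/phi``.  phi = 0 reduces to a conditional
    binomial split.
    """
    if phi < 0:
        raise ValueError("negative dispersion")
    a, b = int(round(a)), int(round(b))
    t = a + b
    if t == 0:
        return 1.0
    support = np.arange(t + 1)
    if phi == 0:
        logp = stats.binom.logpmf(support, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)                       # per-sample mean given total
        r_a, r_b = n_a / phi, n_b / phi
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logp = (stats.nbinom.logpmf(support, r_a, p_a)
                + stats.nbinom.logpmf(support[::-1], r_b, p_b))
        logp -= logsumexp_stable(logp)
    obs = logp[a]
    mask = logp <= obs + 1e-10                      # splits as or less likely
    return float(min(1.0, np.exp(logsumexp_stable(logp[mask]))))


def logsumexp_stable(logp: np.ndarray) -> float:
    m = np.max(logp)
    return float(m + np.log(np.sum(np.exp(logp - m))))


def exact_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
               dispersion, effective_lib_sizes: pd.Series) -> pd.Series:
    """Per-contig two-sided exact NB p-values between two sample groups.

    ``dispersion`` may be a scalar or a per-contig Series.  Counts are first
    rescaled to a common effective library size; the test then conditions on
    each contig's rescaled total.
    """
    joint = pd.concat([counts_a, counts_b], axis=1)
    pseudo = equalize_counts(joint, effective_lib_sizes)
    a_sum = pseudo[counts_a.columns].sum(axis=1).round().astype(int)
    b_sum = pseudo[counts_b.columns].sum(axis=1).round().astype(int)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if np.isscalar(dispersion):
        phi = pd.Series(float(dispersion), index=joint.index)
    else:
        phi = dispersion.reindex(joint.index)
    pvals = [_exact_nb_pvalue(a_sum.iloc[i], b_sum.iloc[i], n_a, n_b, phi.iloc[i])
             for i in range(len(joint))]
    return pd.Series(pvals, index=joint.index, name="p")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_max: float = 0.05, fc_min: float = 2.0
            ) -> pd.DataFrame:
    """Apply the DE gates: FDR strictly below ``fdr_max`` and fold change
    strictly above ``fc_min`` in either direction."""
    out = table.copy()
    out["is_de"] = (out["fdr"] < fdr_max) & (out["logFC"].abs() > np.log2(fc_min))
    out["direction"] = np.select(
        [out["is_de"] & (out["logFC"] > 0), out["is_de"] & (out["logFC"] < 0)],
        ["up", "down"], default="none")
    return out


def de_table(cm: CountMatrix, design: pd.DataFrame, experiment: str,
             min_total: int = 10, fdr_max: float = 0.05, fc_min: float = 2.0,
             logfc_pseudo: float = 0.5) -> pd.DataFrame:
    """Full per-experiment DE analysis on the expressed contigs.

    Filters to the experiment's samples and its expressed set, TMM-normalizes,
    estimates dispersion, runs the exact test, BH-adjusts, and applies the
    FDR/fold-change gates.  logFC is log2 of TMM-normalized group means with a
    pseudo-count of ``logfc_pseudo`` per group.
    """
    from helix_ieg.expression import filter_expressed

    act = samples_for(design, experiment, "Activated")
    ctl = samples_for(design, experiment, "Control")
    sub = filter_expressed(cm.subset_samples(act + ctl), min_total)
    f = tmm_factors(sub.counts)
    eff = sub.library_sizes().astype(float) * f

    pseudo = equalize_counts(sub.counts, eff)
    groups = pd.Series(["Activated" if s in act else "Control" for s in pseudo.columns],
                       index=pseudo.columns)
    disp = estimate_dispersion(pseudo, groups)
    p = exact_test(sub.counts[act], sub.counts[ctl], disp.shrunk, eff)

    mean_act = pseudo[act].mean(axis=1)
    mean_ctl = pseudo[ctl].mean(axis=1)
    logfc = np.log2(mean_act + logfc_pseudo) - np.log2(mean_ctl + logfc_pseudo)
    table = pd.DataFrame({"logFC": logfc, "p": p, "fdr": bh_fdr(p)})
    table.index.name = "contig_id"
    return call_de(table, fdr_max=fdr_max, fc_min=fc_min)


def overlap_hypergeom(set_a, set_b, background_size: int) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two DE sets.

    ``P(X >= |A & B|)`` with ``X ~ Hypergeom(N=background, K=|A|, n=|B|)``.
    """
    set_a, set_b = set(set_a), set(set_b)
    k = len(set_a & set_b)
    if k > min(len(set_a), len(set_b)):
        raise ValueError("overlap exceeds the smaller set")
    if max(len(set_a), len(set_b)) > background_size:
        raise ValueError("set larger than background")
    return float(stats.hypergeom.sf(k - 1, background_size, len(set_a), len(set_b)))


def direction_concordance(logfc_e1: pd.Series, logfc_e2: pd.Series,
                          de_union) -> dict:
    """Direction agreement of a DE-contig union across the two experiments.

    Returns the fractions up-in-both / down-in-both / discordant over the
    union, and a chi-square test (no Yates correction) on the 2x2 table of
    sign(E1) x sign(E2); zero-logFC contigs are excluded from the table.
    """
    union = [c for c in de_union if c in logfc_e1.index and c in logfc_e2.index]
    s1 = np.sign(logfc_e1.loc[union].to_numpy())
    s2 = np.sign(logfc_e2.loc[union].to_numpy())
    n = len(union)
    up_both = int(np.sum((s1 > 0) & (s2 > 0)))
    down_both = int(np.sum((s1 < 0) & (s2 < 0)))
    nz = (s1 != 0) & (s2 != 0)
    table = np.array([[np.sum((s1 > 0) & (s2 > 0)), np.sum((s1 > 0) & (s2 < 0))],
                      [np.sum((s1 < 0) & (s2 > 0)), np.sum((s1 < 0) & (s2 < 0))]],
                     dtype=float)
    if table.sum() and (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = np.nan, np.nan
    return {
        "n_union": n,
        "frac_up_both": up_both / n if n else np.nan,
        "frac_down_both": down_both / n if n else np.nan,
        "frac_discordant": (int(nz.sum()) - up_both - down_both) / n if n else np.nan,
        "table": table,
        "chi2": float(chi2),
        "chi2_p": float(p),
    }
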