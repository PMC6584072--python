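"""Expressed-contig filtering, TMM normalization, RPKM, and classical MDS.

TMM follows the trimmed-mean-of-M-values recipe of Robinson & Oshlack (2010)
as implemented in edgeR: per-sample M and A values against a reference
library on double-positive contigs, 30%/5% two-sided trimming on M and A,
inverse-asymptotic-variance-weighted mean of M, with the resulting factors
re-centred to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from helix_ieg.containers import CountMatrix


def filter_expressed(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Retain contigs whose total count across the matrix's samples is
    strictly greater than ``min_total``.

    Filtering is per experiment: pass a matrix already restricted to one
    experiment's samples to reproduce the per-experiment expressed sets.
    """
    keep = cm.counts.sum(axis=1) > min_total
    return CountMatrix(cm.counts.loc[keep], cm.lengths.loc[keep])


def _choose_reference(counts: np.ndarray) -> int:
    """Reference library: sample whose 75th-percentile count fraction is
    closest to the mean of those fractions."""
    lib = counts.sum(axis=0)
    q75 = np.quantile(counts, 0.75, axis=0) / lib
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> linear)."""
    pos = (obs > 0) & (ref > 0)
    if pos.sum() == 0:
        return 1.0
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method asymptotic variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, re-centred to geometric mean 1."""
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    ref_idx = (_choose_reference(x) if ref_sample is None
               else counts.columns.get_loc(ref_sample))
    f = np.array([_tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                            trim_m, trim_a)
                  for j in range(x.shape[1])])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedMatrix:
    """TMM factors, library sizes and RPKM values for one expressed set."""

    tmm: pd.Series
    lib_sizes: pd.Series
    rpkm: pd.DataFrame

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.tmm


def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         effective_lib_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of (effective) contig length per million reads:
    ``R_gs = K_gs / (l_g / 1e3) / (N_s f_s / 1e6)``."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("non-positive contig length")
    n = effective_lib_sizes.reindex(counts.columns)
    if (n <= 0).any():
        raise ValueError("non-positive effective library size")
    return counts.div(lengths / 1e3, axis=0).div(n / 1e6, axis=1)


def normalize(cm: CountMatrix, use_tmm_lib_sizes: bool = True) -> NormalizedMatrix:
    """Run TMM then RPKM on an (already filtered) count matrix.

    ``use_tmm_lib_sizes`` switches the RPKM denominator between TMM-adjusted
    effective library sizes (default) and raw library sizes.
    """
    f = tmm_factors(cm.counts)
    lib = cm.library_sizes().astype(float)
    eff = lib * f if use_tmm_lib_sizes else lib
    return NormalizedMatrix(tmm=f, lib_sizes=lib,
                            rpkm=rpkm(cm.counts, cm.lengths, eff))


def spearman_dissimilarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample dissimilarity ``1 - Spearman rho`` (average-rank ties).

    Raises on constant columns, where the rank correlation is undefined.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 contigs")
    if (matrix.nunique(axis=0) <= 1).any():
        bad = matrix.columns[matrix.nunique(axis=0) <= 1].tolist()
        raise ValueError(f"constant column(s), Spearman undefined: {bad}")
    rho = matrix.corr(method="spearman")
    d = 1.0 - rho
    np.fill_diagonal(d.values, 0.0)
    return d


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 2
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS by double-centring and eigendecomposition.

    Returns coordinates from the top-``k`` positive-eigenvalue pairs (fewer
    columns when fewer positive eigenvalues exist) and the full eigenvalue
    spectrum (descending).  Column signs are fixed so the largest-magnitude
    loading in each dimension is positive.
    """
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(d))
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-12))
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for col in range(k_eff):
        i = int(np.argmax(np.abs(coords[:, col])))
        if coords[i, col] < 0:
            coords[:, col] = -coords[:, col]
    cols = [f"dim{i + 1}" for i in range(k_eff)]
    return pd.DataFrame(coords, index=index, columns=cols), evals
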