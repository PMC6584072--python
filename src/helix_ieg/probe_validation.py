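"""In situ probe design and wet-lab validation statistics.

Probe design enumerates junction-spanning windows under length and GC
constraints (the junction must sit strictly inside each probe so it can only
hybridize spliced transcript, not genomic DNA).  Validation statistics cover
2^-ddCt relative qPCR expression, exact Mann-Whitney rank tests by full
enumeration of group assignments, and Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from helix_ieg.assembly_qc import gc_content, revcomp

#: Full-enumeration cap for the exact rank test: C(20, 10) assignments.
ENUMERATION_CAP = 200_000


@dataclass
class ProbeCandidate:
    contig_id: str
    start: int                 # 0-based, half-open on the contig
    end: int
    sequence: str              # sense orientation (contig strand)
    antisense: str             # reverse complement, for RNA-targeting probes
    length: int
    gc: float
    junction_offset: int       # junction position within the probe


def design_probes(contig_seq: str, junction_pos: int,
                  contig_id: str = "contig",
                  length_range: tuple[int, int] = (45, 55),
                  gc_range: tuple[float, float] = (40.0, 50.0),
                  flank_min: int = 10) -> list[ProbeCandidate]:
    """All junction-spanning windows satisfying the design constraints, ranked.

    Windows must contain the exon-exon junction with at least ``flank_min``
    nt on each side, a length within ``length_range`` and GC within
    ``gc_range`` (both inclusive).  Ranking: closest GC to the middle of the
    GC window, then length closest to 50 nt, then leftmost start.  Returns an
    empty list when no window qualifies.
    """
    seq = contig_seq.upper()
    n = len(seq)
    if not 0 < junction_pos < n:
        raise ValueError("junction must lie strictly inside the contig")
    gc_mid = (gc_range[0] + gc_range[1]) / 2
    candidates = []
    for length in range(length_range[0], length_range[1] + 1):
        lo = max(0, junction_pos - (length - flank_min))
        hi = min(n - length, junction_pos - flank_min)
        for start in range(lo, hi + 1):
            end = start + length
            window = seq[start:end]
            gc = gc_content(window)
            if not gc_range[0] <= gc <= gc_range[1]:
                continue
            candidates.append(ProbeCandidate(
                contig_id=contig_id, start=start, end=end, sequence=window,
                antisense=revcomp(window), length=length,
                gc=gc, junction_offset=junction_pos - start))
    candidates.sort(key=lambda c: (abs(c.gc - gc_mid), abs(c.length - 50), c.start))
    return candidates


def ddct(measurements: pd.DataFrame, calibrator_group: str,
         target_col: str = "ct_target") -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``measurements`` needs one row per sample with columns ``sample_id``,
    ``group``, ``ct_target`` and one or more reference-gene columns starting
    with ``ct_ref``.  Replicate Cts should be averaged beforehand.  The
    reference normalizer is the geometric mean of the reference genes'
    expression, i.e. the arithmetic mean of their Cts; samples missing the
    target or every reference Ct are dropped with a warning.
    """
    ref_cols = [c for c in measurements.columns if c.startswith("ct_ref")]
    if not ref_cols:
        raise ValueError("no reference Ct columns (ct_ref*)")
    df = measurements.copy()
    ref_ct = df[ref_cols].mean(axis=1)
    bad = df[target_col].isna() | ref_ct.isna()
    if bad.any():
        import warnings
        warnings.warn(f"dropping {int(bad.sum())} sample(s) with missing Ct")
        df, ref_ct = df[~bad], ref_ct[~bad]
    dct = df[target_col] - ref_ct
    calib = dct[df["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    ddct_vals = dct - calib.mean()
    out = df[["sample_id", "group"]].copy()
    out["delta_ct"] = dct
    out["delta_delta_ct"] = ddct_vals
    out["relative_expression"] = 2.0 ** (-ddct_vals)
    return out


@dataclass
class RankTestResult:
    u: float                    # U statistic of x: #{x_i > y_j} + 1/2 ties
    n1: int
    n2: int
    alternative: str
    p_value: float
    method: str                 # 'exact' or 'normal'


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_exact(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U test, permutation-exact whenever enumerable.

    The exact p-value enumerates all ``C(n1+n2, n1)`` assignments of the
    pooled observed values to the two groups (valid with ties); above
    :data:`ENUMERATION_CAP` assignments, a normal approximation with tie
    correction is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    u_obs = _u_statistic(x, y)

    if math.comb(n1 + n2, n1) <= ENUMERATION_CAP:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        us = np.array([_u_statistic(pooled[list(c)],
                                    pooled[[i for i in idx if i not in set(c)]])
                       for c in combinations(idx, n1)])
        eps = 1e-9
        p_greater = np.mean(us >= u_obs - eps)
        p_less = np.mean(us <= u_obs + eps)
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            mean_u = n1 * n2 / 2
            p = min(1.0, float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - eps)))
        return RankTestResult(u_obs, n1, n2, alternative, float(p), "exact")

    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankTestResult(u_obs, n1, n2, alternative, float(res.pvalue), "normal")


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``; m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)
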