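"""Assembly quality metrics for a de novo transcriptome.

Nx contig-size statistics, per-contig GC content, a longest-open-frame ORF
percentage, and reciprocal best-hit proteome coverage against a reference
proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    n30: int
    n50: int
    n70: int
    median_gc: float
    median_orf_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def nx_statistic(lengths, fraction: float) -> int:
    """Contig size at which ``fraction`` of assembled bases lie in contigs of
    that length or greater.

    E.g. N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total.
    """
    lengths = np.asarray(list(lengths))
    if lengths.size == 0:
        raise ValueError("empty length list")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    idx = int(np.searchsorted(cum, fraction * cum[-1]))
    return int(desc[idx])


def gc_content(seq: str) -> float:
    """GC percentage; N/ambiguity characters are excluded from the denominator."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / denom


def orf_fraction(seq: str) -> float:
    """Longest-open-frame percentage over all six reading frames.

    100 * 3 * (maximum run of consecutive non-stop codons in any frame of the
    sequence or its reverse complement) / sequence length.  The run need not
    start at ATG; this is a frame-openness metric, not gene calling.
    """
    s = seq.upper()
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon")
    best = 0
    for strand in (s, revcomp(s)):
        for frame in range(3):
            run = 0
            for i in range(frame, len(strand) - 2, 3):
                if strand[i:i + 3] in STOP_CODONS:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
    return 100.0 * 3 * best / len(s)


def _best_hits_by_query(hits: pd.DataFrame, evalue_max: float) -> pd.Series:
    """Best valid subject per query: lowest e-value, ties by highest bitscore
    then lexicographic subject id (deterministic)."""
    valid = hits[hits["evalue"] < evalue_max]
    if valid.empty:
        return pd.Series(dtype=object)
    ranked = valid.sort_values(["qseqid", "evalue", "bitscore", "sseqid"],
                               ascending=[True, True, False, True],
                               kind="mergesort")
    best = ranked.drop_duplicates("qseqid", keep="first")
    return best.set_index("qseqid")["sseqid"]


def reciprocal_best_matches(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                            evalue_max: float = 1e-5,
                            n_b_total: int | None = None
                            ) -> tuple[set[tuple[str, str]], float]:
    """Reciprocal best-hit pairs between sets A and B plus coverage of B.

    A pair ``(a, b)`` is returned iff ``b`` is ``a``'s best valid hit in the
    A->B table and ``a`` is ``b``'s best valid hit in the B->A table.
    Coverage is the fraction of B ids (denominator ``n_b_total`` when given,
    else all distinct B query ids in the B->A table) matched reciprocally.
    """
    best_ab = _best_hits_by_query(hits_ab, evalue_max)
    best_ba = _best_hits_by_query(hits_ba, evalue_max)
    pairs = {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}
    if n_b_total is None:
        n_b_total = hits_ba["qseqid"].nunique() if len(hits_ba) else 0
    coverage = len({b for _, b in pairs}) / n_b_total if n_b_total else 0.0
    return pairs, coverage


def assembly_stats(seqs: dict[str, str]) -> AssemblyStats:
    """Full QC report over a contig set (medians are per-contig, unweighted)."""
    lengths = [len(s) for s in seqs.values()]
    gcs = [gc_content(s) for s in seqs.values()]
    orfs = [orf_fraction(s) for s in seqs.values() if len(s) >= 3]
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bases=int(sum(lengths)),
        n30=nx_statistic(lengths, 0.3),
        n50=nx_statistic(lengths, 0.5),
        n70=nx_statistic(lengths, 0.7),
        median_gc=float(np.median(gcs)),
        median_orf_pct=float(np.median(orfs)),
    )
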