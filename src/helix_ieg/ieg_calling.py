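"""Protein-level IEG calling: the >=80% direction-consistency statistic.

Contig-level expression changes are aggregated to annotated proteins.  A
protein passes when at least 80% of *all* its mapped contigs (DE and non-DE
alike) changed in the same direction after activation, under either of two
direction modes: ``both`` (same sign in both experiments) or ``either``
(signed in at least one experiment without a conflicting sign in the other).
Significance of the observed pass percentage (or of an upregulated-contig
fraction) is assessed by resampling, for each protein, the same number of
contigs from the expressed-direction pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

THRESHOLD_80 = 0.80


def contig_directions(logfc_by_experiment: dict[str, pd.Series],
                      mode: str = "both") -> pd.Series:
    """Per-contig direction ('up' / 'down' / 'none') across experiments.

    ``both``: up iff logFC > 0 in every experiment where the contig is
    expressed AND it is expressed in all of them; ``either``: up iff logFC > 0
    in at least one experiment and not < 0 in any other (conflicting signs
    give 'none').  logFC exactly 0 counts as neither direction.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    frames = pd.DataFrame(logfc_by_experiment)
    signs = np.sign(frames.to_numpy())
    present = ~np.isnan(signs)
    n_pos = np.nansum(signs > 0, axis=1)
    n_neg = np.nansum(signs < 0, axis=1)
    n_present = present.sum(axis=1)
    n_exp = frames.shape[1]
    if mode == "both":
        up = (n_present == n_exp) & (n_pos == n_exp)
        down = (n_present == n_exp) & (n_neg == n_exp)
    else:
        up = (n_pos >= 1) & (n_neg == 0)
        down = (n_neg >= 1) & (n_pos == 0)
    out = np.where(up, "up", np.where(down, "down", "none"))
    return pd.Series(out, index=frames.index, name="direction")


@dataclass
class ProteinCall:
    protein: str
    contigs: list[str]
    n_contigs: int
    frac_up: float
    frac_down: float
    passes_80: bool
    n_de: int = 0
    candidate_ieg: bool = False


def protein_consistency(protein_contigs: dict[str, list[str]],
                        directions: pd.Series,
                        threshold: float = THRESHOLD_80) -> pd.DataFrame:
    """Direction fractions over ALL mapped contigs per protein.

    ``passes_80`` uses an inclusive >= threshold ("no less than 80%").
    """
    rows = []
    for prot, contigs in protein_contigs.items():
        if not contigs:
            raise ValueError(f"protein {prot} has an empty contig set")
        d = directions.reindex(contigs).fillna("none")
        n = len(contigs)
        frac_up = (d == "up").sum() / n
        frac_down = (d == "down").sum() / n
        rows.append({
            "protein": prot, "n_contigs": n,
            "frac_up": frac_up, "frac_down": frac_down,
            "passes_80": max(frac_up, frac_down) >= threshold,
            "passes_80_up": frac_up >= threshold,
        })
    return pd.DataFrame(rows).set_index("protein")


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def _directions_to_int(directions: pd.Series) -> np.ndarray:
    return np.select([directions == "up", directions == "down"], [1, -1], 0)


def permute_protein_consistency(protein_contigs: dict[str, list[str]],
                                directions: pd.Series,
                                expressed_directions: pd.Series,
                                n_permutations: int = 1000,
                                seed: int = 0,
                                threshold: float = THRESHOLD_80,
                                up_only: bool = False) -> PermutationResult:
    """Permutation p-value for the percentage of proteins passing the rule.

    Each iteration resamples, independently for every protein, the same
    number of contigs without replacement from the expressed-contig direction
    pool, and recomputes the pass percentage.  ``p = (r + 1) / (B + 1)`` where
    ``r`` counts null percentages >= observed.
    """
    table = protein_consistency(protein_contigs, directions, threshold)
    col = "passes_80_up" if up_only else "passes_80"
    observed = 100.0 * table[col].mean()
    pool = _directions_to_int(expressed_directions)
    sizes = np.array([len(c) for c in protein_contigs.values()])
    if sizes.max() > len(pool):
        raise ValueError("direction pool smaller than the largest protein's contig set")
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        passed = 0
        for n in sizes:
            draw = pool[rng.choice(len(pool), size=n, replace=False)]
            up = np.mean(draw == 1)
            down = np.mean(draw == -1)
            score = up if up_only else max(up, down)
            passed += score >= threshold
        null[b] = 100.0 * passed / len(sizes)
    p = (np.sum(null >= observed) + 1) / (n_permutations + 1)
    return PermutationResult(observed, null, float(p), n_permutations, seed)


def permute_contig_fraction(observed_set_size: int,
                            observed_fraction_up: float,
                            expressed_directions: pd.Series,
                            n_permutations: int = 1000,
                            seed: int = 0) -> PermutationResult:
    """Permutation p-value for an observed fraction of upregulated contigs.

    Each iteration draws ``observed_set_size`` contigs without replacement
    from the expressed-direction pool and measures the upregulated fraction.
    """
    pool = _directions_to_int(expressed_directions)
    if observed_set_size > len(pool):
        raise ValueError("set size exceeds the direction pool")
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        draw = pool[rng.choice(len(pool), size=observed_set_size, replace=False)]
        null[b] = np.mean(draw == 1)
    p = (np.sum(null >= observed_fraction_up) + 1) / (n_permutations + 1)
    return PermutationResult(observed_fraction_up, null, float(p),
                             n_permutations, seed)


def call_iegs(protein_contigs: dict[str, list[str]],
              directions: pd.Series,
              de_flags: pd.Series,
              threshold: float = THRESHOLD_80) -> pd.DataFrame:
    """Candidate IEG proteins: consistently annotated proteins with at least
    one DE contig whose mapped contigs pass the 80% rule upward.

    ``protein_contigs`` should already be restricted to consistently
    annotated proteins (protein_group_id -> mapped contigs); ``de_flags`` is
    a boolean per-contig Series (DE in at least one experiment).
    """
    table = protein_consistency(protein_contigs, directions, threshold)
    n_de = pd.Series({p: int(de_flags.reindex(c).fillna(False).sum())
                      for p, c in protein_contigs.items()})
    table["n_de"] = n_de
    table["candidate_ieg"] = (table["n_de"] >= 1) & table["passes_80_up"]
    return table
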