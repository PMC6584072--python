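"""End-to-end orchestration: counts + hit tables -> candidate IEG proteins.

Chains per-experiment differential expression, cross-species consistent
annotation, protein-level direction consistency and the resampling null into
one call, mirroring the order of the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from helix_ieg import annotation as ann
from helix_ieg import diffexpr as de
from helix_ieg import ieg_calling as ieg
from helix_ieg.containers import CountMatrix


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]          # experiment -> DE table
    annotations: dict                           # contig -> ContigAnnotation
    protein_contigs: dict[str, list[str]]       # consistent protein groups
    directions: pd.Series
    protein_calls: pd.DataFrame
    consistency_perm: ieg.PermutationResult | None
    overlap_p: float
    concordance: dict

    @property
    def candidates(self) -> list[str]:
        return self.protein_calls.index[self.protein_calls["candidate_ieg"]].tolist()


def protein_groups_from_annotations(annotations: dict,
                                    restrict_to=None) -> dict[str, list[str]]:
    """Consistently annotated contigs grouped by representative protein."""
    groups: dict[str, list[str]] = {}
    for contig, a in annotations.items():
        if a.category != "consistent":
            continue
        if restrict_to is not None and contig not in restrict_to:
            continue
        groups.setdefault(a.protein_group_id, []).append(contig)
    return {p: sorted(c) for p, c in sorted(groups.items())}


def run_pipeline(cm: CountMatrix,
                 design: pd.DataFrame,
                 blastx: dict[str, pd.DataFrame],
                 blastp: dict[tuple[str, str], pd.DataFrame],
                 mode: str = "both",
                 min_total: int = 10,
                 fdr_max: float = 0.05,
                 fc_min: float = 2.0,
                 n_permutations: int = 1000,
                 seed: int = 0,
                 de_proteins_only: bool = True) -> PipelineResult:
    """Run DE -> annotation -> protein consistency -> permutation null.

    ``de_proteins_only`` restricts the protein call table (and its
    permutation null) to proteins with at least one DE contig, matching the
    original candidate definition; set False to score every consistently
    annotated protein.
    """
    experiments = sorted(design["experiment"].unique())
    de_tables = {e: de.de_table(cm, design, e, min_total=min_total,
                                fdr_max=fdr_max, fc_min=fc_min)
                 for e in experiments}

    expressed = {e: set(t.index) for e, t in de_tables.items()}
    expressed_union = set().union(*expressed.values())

    drafts = ann.best_hits(blastx)
    drafts = {c: a for c, a in drafts.items() if c in expressed_union}
    homology = ann.build_homology(blastp)
    annotations = ann.consistent_annotation(drafts, homology)

    logfc = {e: t["logFC"] for e, t in de_tables.items()}
    directions = ieg.contig_directions(logfc, mode=mode)

    de_any = pd.Series(False, index=sorted(expressed_union))
    for t in de_tables.values():
        de_any.loc[t.index[t["is_de"]]] = True

    groups = protein_groups_from_annotations(annotations, restrict_to=expressed_union)
    if de_proteins_only:
        groups = {p: c for p, c in groups.items()
                  if de_any.reindex(c).fillna(False).any()}

    if groups:
        calls = ieg.call_iegs(groups, directions, de_any)
        pool = directions.reindex(sorted(expressed_union)).fillna("none")
        perm = ieg.permute_protein_consistency(
            groups, directions, pool, n_permutations=n_permutations,
            seed=seed, up_only=True)
    else:
        calls = pd.DataFrame(columns=["n_contigs", "frac_up", "frac_down",
                                      "passes_80", "passes_80_up", "n_de",
                                      "candidate_ieg"])
        perm = None

    de_sets = {e: set(t.index[t["is_de"]]) for e, t in de_tables.items()}
    if len(experiments) >= 2:
        e1, e2 = experiments[0], experiments[1]
        overlap_p = de.overlap_hypergeom(de_sets[e1], de_sets[e2],
                                         background_size=len(expressed[e1]))
        union = sorted(de_sets[e1] | de_sets[e2])
        concordance = de.direction_concordance(logfc[e1], logfc[e2], union)
    else:
        overlap_p, concordance = float("nan"), {}

    return PipelineResult(de_tables=de_tables, annotations=annotations,
                          protein_contigs=groups, directions=directions,
                          protein_calls=calls, consistency_perm=perm,
                          overlap_p=overlap_p, concordance=concordance)
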