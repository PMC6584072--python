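"""Cross-species contig annotation with a homology-consistency rule.

Each expressed contig keeps, per species, its best valid protein hit
(e-value < 1e-5; ties by bitscore then subject id).  Proteomes of the five
annotation species are related by a BLASTP-derived homology index (top five
valid alignments per query and target species).  A contig with best hits in
two or more species is *consistently annotated* when some anchor species'
best protein is homologous to the best protein of every other hit species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Anchor preference when several species qualify (well-annotated proteomes
#: first), used only to pick the representative protein label.
ANCHOR_PREFERENCE = ("Ac", "Bg", "Dm", "Ce", "Tr")

EVALUE_MAX = 1e-5


@dataclass
class ContigAnnotation:
    contig_id: str
    best: dict[str, str]                 # species -> best protein
    category: str = "unannotated"        # one_species | inconsistent | consistent
    consistent: bool | None = None       # None when hits in <2 species
    protein_group_id: str | None = None


@dataclass
class HomologyIndex:
    """(species_a, protein_a, species_b) -> top-5 homologous proteins in b."""

    top5: dict[tuple[str, str, str], frozenset] = field(default_factory=dict)

    def homologous(self, sp_a: str, prot_a: str, sp_b: str, prot_b: str,
                   symmetric: bool = True) -> bool:
        fwd = prot_b in self.top5.get((sp_a, prot_a, sp_b), ())
        if not symmetric:
            return fwd
        return fwd or prot_a in self.top5.get((sp_b, prot_b, sp_a), ())


def best_hits(blastx: dict[str, pd.DataFrame], evalue_max: float = EVALUE_MAX
              ) -> dict[str, ContigAnnotation]:
    """Per contig, the best valid hit in each species.

    ``blastx`` maps species label -> outfmt-6 DataFrame of contig->protein
    hits.  Contigs with no valid hit anywhere are omitted (unannotated).
    """
    drafts: dict[str, ContigAnnotation] = {}
    for sp, df in blastx.items():
        valid = df[df["evalue"] < evalue_max]
        if valid.empty:
            continue
        ranked = valid.sort_values(["qseqid", "evalue", "bitscore", "sseqid"],
                                   ascending=[True, True, False, True],
                                   kind="mergesort").drop_duplicates("qseqid")
        for contig, prot in zip(ranked["qseqid"], ranked["sseqid"]):
            drafts.setdefault(contig, ContigAnnotation(contig, {})).best[sp] = prot
    return drafts


def build_homology(blastp: dict[tuple[str, str], pd.DataFrame],
                   evalue_max: float = EVALUE_MAX, top_k: int = 5
                   ) -> HomologyIndex:
    """Top-``top_k`` valid BLASTP alignments per (query protein, target species)."""
    index: dict[tuple[str, str, str], frozenset] = {}
    for (sp_a, sp_b), df in blastp.items():
        valid = df[df["evalue"] < evalue_max]
        if valid.empty:
            continue
        ranked = valid.sort_values(["qseqid", "evalue", "bitscore", "sseqid"],
                                   ascending=[True, True, False, True],
                                   kind="mergesort")
        top = ranked.groupby("qseqid", sort=False).head(top_k)
        for q, grp in top.groupby("qseqid", sort=False):
            index[(sp_a, q, sp_b)] = frozenset(grp["sseqid"])
    return HomologyIndex(index)


def consistent_annotation(drafts: dict[str, ContigAnnotation],
                          homology: HomologyIndex,
                          symmetric: bool = True,
                          all_pairs: bool = False) -> dict[str, ContigAnnotation]:
    """Apply the cross-species consistency rule to best-hit drafts.

    Default (anchor) mode: consistent iff some hit species' best protein is
    homologous to every other hit species' best protein; the representative
    ``protein_group_id`` is the qualifying anchor's protein, anchors tried in
    :data:`ANCHOR_PREFERENCE` order.  ``all_pairs=True`` instead requires all
    species pairs to be mutually homologous.
    """
    out: dict[str, ContigAnnotation] = {}
    for contig, draft in drafts.items():
        ann = ContigAnnotation(contig, dict(draft.best))
        species = sorted(ann.best)
        if len(species) == 1:
            ann.category = "one_species"
            ann.protein_group_id = ann.best[species[0]]
        else:
            ordered = [sp for sp in ANCHOR_PREFERENCE if sp in species]
            ordered += [sp for sp in species if sp not in ordered]
            anchors = [sp for sp in ordered
                       if all(homology.homologous(sp, ann.best[sp], o, ann.best[o],
                                                  symmetric=symmetric)
                              for o in species if o != sp)]
            if all_pairs:
                ok = all(homology.homologous(a, ann.best[a], b, ann.best[b],
                                             symmetric=symmetric)
                         for i, a in enumerate(species) for b in species[i + 1:])
                anchors = anchors if ok else []
            ann.consistent = bool(anchors)
            ann.category = "consistent" if anchors else "inconsistent"
            if anchors:
                ann.protein_group_id = ann.best[anchors[0]]
        out[contig] = ann
    return out


def annotation_summary(annotations: dict[str, ContigAnnotation],
                       expressed_sets: dict[str, set] | None = None
                       ) -> pd.DataFrame:
    """Counts of the three annotation categories, optionally per expressed set."""
    cats = ("one_species", "inconsistent", "consistent")
    sets = expressed_sets or {"all": set(annotations)}
    rows = {}
    for name, contigs in sets.items():
        sub = [a for c, a in annotations.items() if c in contigs]
        rows[name] = {cat: sum(a.category == cat for a in sub) for cat in cats}
        rows[name]["annotated"] = len(sub)
    return pd.DataFrame(rows).T


def annotation_table(annotations: dict[str, ContigAnnotation]) -> pd.DataFrame:
    """Flat per-contig table (one row per annotated contig)."""
    rows = []
    for contig, ann in sorted(annotations.items()):
        row = {"contig_id": contig, "category": ann.category,
               "protein_group_id": ann.protein_group_id}
        for sp, prot in ann.best.items():
            row[f"best_{sp}"] = prot
        rows.append(row)
    return pd.DataFrame(rows)
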