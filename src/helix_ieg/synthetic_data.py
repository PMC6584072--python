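"""Synthetic pipeline inputs with known ground truth.

Emulates the statistical structure of a paired activated/control CNS
stimulation study on a fragmented de novo transcriptome: negative-binomial
contig counts with per-individual offsets shared by an individual's paired
samples, multi-contig fragmentation per underlying protein, and five-species
sequence-similarity hit tables with a controlled fraction of cross-species
homology-consistent proteins.

Counts follow ``K_gs ~ NB(mean = (l_g/1e3) * (N_s/1e6) * b_g * e_i * F_gs,
Var = mu + phi * mu^2)`` where ``F_gs = effect_fc`` when contig ``g`` is a
planted IEG contig and sample ``s`` is activated, else 1.  ``phi = 0``
degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from helix_ieg import io as hio
from helix_ieg.containers import DESIGN_COLUMNS, CountMatrix

#: Species labels used for annotation: Biomphalaria glabrata, Aplysia
#: californica, Caenorhabditis elegans, Drosophila melanogaster,
#: Takifugu rubripes.
DEFAULT_SPECIES = ("Bg", "Ac", "Ce", "Dm", "Tr")


@dataclass
class SimParams:
    """Parameters of the synthetic study.

    Defaults mirror the study design: two experiments with six individuals
    each, one activated and one paired control sample per individual, and an
    average fragmentation of about three contigs per protein.
    """

    n_proteins: int = 200
    frac_ieg: float = 0.25
    effect_fc: float = 3.0                      # fold change in activated samples
    contigs_per_protein: tuple[int, int] = (1, 5)
    n_orphan_contigs: int = 50
    n_individuals_per_experiment: int = 6
    dispersion: float = 0.1                     # NB phi, Var = mu + phi mu^2
    base_mean_log_range: tuple[float, float] = (0.0, 2.0)   # log10 of b_g
    individual_sd: float = 0.2                  # sd of log-normal offsets e_i
    lib_size_range: tuple[int, int] = (1_000_000, 3_000_000)
    contig_length_range: tuple[int, int] = (300, 3000)
    gc_fraction: float = 0.41
    species_list: tuple[str, ...] = DEFAULT_SPECIES
    frac_consistent_homology: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_ieg <= 1:
            raise ValueError("frac_ieg must be in [0, 1]")
        if not 0 <= self.frac_consistent_homology <= 1:
            raise ValueError("frac_consistent_homology must be in [0, 1]")
        if self.effect_fc < 1:
            raise ValueError("effect_fc must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.contigs_per_protein[0] < 1:
            raise ValueError("contigs_per_protein minimum must be >= 1")
        if self.n_individuals_per_experiment < 1:
            raise ValueError("need at least one individual per experiment")
        if self.lib_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth backing parameter-recovery tests."""

    protein_ids: list[str]
    contig_protein: dict[str, str | None]       # orphan contigs map to None
    contig_is_ieg: dict[str, bool]
    contig_lengths: dict[str, int]
    base_means: dict[str, float]
    protein_consistent: dict[str, bool]         # cross-species homology flag
    ieg_proteins: list[str] = field(default_factory=list)

    def contigs_of(self, protein: str) -> list[str]:
        return [c for c, p in self.contig_protein.items() if p == protein]


def _make_design(params: SimParams) -> pd.DataFrame:
    rows = []
    k = 0
    individual = 0
    for exp in ("E1", "E2"):
        for _ in range(params.n_individuals_per_experiment):
            individual += 1
            for cond in ("Control", "Activated"):
                k += 1
                hemi = "Left" if (individual + (cond == "Activated")) % 2 else "Right"
                rows.append((f"Sample{k}", exp, hemi, cond, individual))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def simulate_counts(params: SimParams) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate the count matrix, design table and planted truth.

    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    n_ieg = int(round(params.frac_ieg * params.n_proteins))
    ieg_proteins = set(proteins[:n_ieg])  # ids carry no information downstream
    lo, hi = params.contigs_per_protein
    n_contigs_per = rng.integers(lo, hi + 1, size=params.n_proteins)

    contig_protein: dict[str, str | None] = {}
    contig_is_ieg: dict[str, bool] = {}
    k = 0
    for prot, n_c in zip(proteins, n_contigs_per):
        for _ in range(n_c):
            cid = f"c{k:06d}"
            contig_protein[cid] = prot
            contig_is_ieg[cid] = prot in ieg_proteins
            k += 1
    for _ in range(params.n_orphan_contigs):
        cid = f"c{k:06d}"
        contig_protein[cid] = None
        contig_is_ieg[cid] = False
        k += 1
    contig_ids = list(contig_protein)
    n_contigs = len(contig_ids)

    lengths = rng.integers(params.contig_length_range[0],
                           params.contig_length_range[1] + 1, size=n_contigs)
    log_lo, log_hi = params.base_mean_log_range
    base_means = 10.0 ** rng.uniform(log_lo, log_hi, size=n_contigs)

    design = _make_design(params)
    n_samples = len(design)
    lib_sizes = rng.integers(params.lib_size_range[0],
                             params.lib_size_range[1] + 1, size=n_samples)
    individuals = design["individual"].to_numpy()
    uniq_ind = np.unique(individuals)
    ind_offset = dict(zip(
        uniq_ind,
        np.exp(rng.normal(0.0, params.individual_sd, size=len(uniq_ind)))))
    activated = (design["condition"] == "Activated").to_numpy()
    is_ieg = np.array([contig_is_ieg[c] for c in contig_ids])

    # mean model: mu_gs = (l_g / 1e3) * (N_s / 1e6) * b_g * e_i * F_gs
    mu = (lengths / 1e3 * base_means)[:, None] * (lib_sizes / 1e6)[None, :]
    mu = mu * np.array([ind_offset[i] for i in individuals])[None, :]
    fc = np.ones((n_contigs, n_samples))
    fc[np.ix_(is_ieg, activated)] = params.effect_fc
    mu = mu * fc
    if not np.all(np.isfinite(mu)):
        raise ValueError(f"non-finite NB means under parameters: {params!r}")

    if params.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        pd.DataFrame(counts, index=contig_ids, columns=design["sample_id"].tolist()),
        pd.Series(lengths, index=contig_ids, name="length"),
    )

    n_cons = int(round(params.frac_consistent_homology * params.n_proteins))
    cons_proteins = set(rng.permutation(proteins)[:n_cons])
    truth = SyntheticTruth(
        protein_ids=proteins,
        contig_protein=contig_protein,
        contig_is_ieg=contig_is_ieg,
        contig_lengths=dict(zip(contig_ids, (int(x) for x in lengths))),
        base_means=dict(zip(contig_ids, (float(x) for x in base_means))),
        protein_consistent={p: p in cons_proteins for p in proteins},
        ieg_proteins=sorted(ieg_proteins),
    )
    return cm, design, truth


def _hit_row(q: str, s: str, evalue: float, rng) -> list:
    aln = int(rng.integers(50, 400))
    pident = float(np.round(rng.uniform(30, 95), 1))
    bitscore = max(25.0, np.round(-10.0 * np.log10(max(evalue, 1e-180)) + rng.uniform(0, 20), 1))
    return [q, s, pident, aln, int(aln * (1 - pident / 100)), 0,
            1, aln, 1, aln, evalue, bitscore]


def _log_uniform(rng, lo: float, hi: float, size=None):
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def simulate_hit_tables(truth: SyntheticTruth, params: SimParams
                        ) -> tuple[dict[str, pd.DataFrame],
                                   dict[tuple[str, str], pd.DataFrame]]:
    """Build BLASTX-style contig->protein and BLASTP-style protein->protein tables.

    Every non-orphan contig gets a valid best hit (e < 1e-5) to its truth
    protein's ortholog in each species, plus an invalid decoy hit.  Proteins
    flagged homology-consistent produce mutually homologous records across all
    species pairs; for an inconsistent protein, the first species' best hit is
    redirected to an unrelated decoy protein with no homology support, so no
    anchor species can certify the contig.  Orphan contigs only receive hits
    above the 1e-5 validity threshold.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    species = list(params.species_list)
    ortho = {(p, sp): f"{sp}|{p}" for p in truth.protein_ids for sp in species}
    decoy = {sp: f"{sp}|DECOY" for sp in species}

    blastx: dict[str, list] = {sp: [] for sp in species}
    for contig, prot in truth.contig_protein.items():
        if prot is None:
            for sp in species:
                blastx[sp].append(_hit_row(contig, ortho[(truth.protein_ids[0], sp)],
                                           _log_uniform(rng, 1e-4, 1.0), rng))
            continue
        consistent = truth.protein_consistent[prot]
        for j, sp in enumerate(species):
            target = decoy[sp] if (not consistent and j == 0) else ortho[(prot, sp)]
            blastx[sp].append(_hit_row(contig, target, _log_uniform(rng, 1e-180, 1e-6), rng))
            # worse, invalid secondary hit exercising best-hit selection
            other = truth.protein_ids[int(rng.integers(len(truth.protein_ids)))]
            blastx[sp].append(_hit_row(contig, ortho[(other, sp)],
                                       _log_uniform(rng, 1e-4, 1.0), rng))

    blastp: dict[tuple[str, str], list] = {}
    for sp1 in species:
        for sp2 in species:
            if sp1 == sp2:
                continue
            rows = []
            for p in truth.protein_ids:
                if truth.protein_consistent[p]:
                    rows.append(_hit_row(ortho[(p, sp1)], ortho[(p, sp2)],
                                         _log_uniform(rng, 1e-180, 1e-6), rng))
                # invalid decoy record (above threshold) for every protein
                rows.append(_hit_row(ortho[(p, sp1)], ortho[(p, sp2)],
                                     _log_uniform(rng, 1e-4, 1.0), rng))
            blastp[(sp1, sp2)] = pd.DataFrame(rows, columns=hio.OUTFMT6_COLUMNS)

    blastx_dfs = {sp: pd.DataFrame(rows, columns=hio.OUTFMT6_COLUMNS)
                  for sp, rows in blastx.items()}
    return blastx_dfs, blastp


def simulate_sequences(truth: SyntheticTruth, params: SimParams) -> dict[str, str]:
    """Random nucleotide sequences matching the truth lengths and GC target."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 13]))
    g = params.gc_fraction / 2
    a = (1 - params.gc_fraction) / 2
    bases = np.array(list("ACGT"))
    probs = [a, g, g, a]
    return {cid: "".join(rng.choice(bases, size=n, p=probs))
            for cid, n in truth.contig_lengths.items()}


def write_fixtures(out_dir,
                   counts: CountMatrix,
                   design: pd.DataFrame,
                   truth: SyntheticTruth,
                   blastx: dict[str, pd.DataFrame],
                   blastp: dict[tuple[str, str], pd.DataFrame],
                   sequences: dict[str, str] | None = None) -> dict[str, Path]:
    """Write the complete fixture set readable by every downstream module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = out / "counts.tsv"
    hio.write_counts(counts.counts, paths["counts"])
    paths["lengths"] = out / "lengths.tsv"
    hio.write_lengths(counts.lengths, paths["lengths"])
    paths["design"] = out / "design.tsv"
    hio.write_design(design, paths["design"])
    for sp, df in blastx.items():
        p = out / f"blastx_{sp}.tsv"
        hio.write_hit_table(df, p)
        paths[f"blastx_{sp}"] = p
    for (sp1, sp2), df in blastp.items():
        p = out / f"blastp_{sp1}_{sp2}.tsv"
        hio.write_hit_table(df, p)
        paths[f"blastp_{sp1}_{sp2}"] = p
    if sequences is not None:
        paths["fasta"] = out / "contigs.fasta"
        hio.write_fasta(sequences, paths["fasta"])
    paths["truth"] = out / "truth.json"
    hio.write_json(asdict(truth), paths["truth"])
    return paths


def simulate_all(params: SimParams, out_dir=None, with_sequences: bool = False):
    """Convenience wrapper running all generators (and optionally writing files)."""
    counts, design, truth = simulate_counts(params)
    blastx, blastp = simulate_hit_tables(truth, params)
    seqs = simulate_sequences(truth, params) if with_sequences else None
    if out_dir is not None:
        write_fixtures(out_dir, counts, design, truth, blastx, blastp, seqs)
    return counts, design, truth, blastx, blastp, seqs
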