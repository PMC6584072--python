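# Methods

This note documents the statistical model behind each stage, the defaults
and why, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Study design being modeled

Two paired stimulation experiments on the snail CNS: in E1 one half of the
parietal ganglia network is activated (serotonin plus the translation
inhibitor anisomycin) with the contralateral half as self-control; in E2 a
dissected medial part containing the giant Pa2/Pa3 interneurons is treated
the same way. Six individuals per experiment, one activated and one control
sample each — 24 samples total. Expression is quantified per assembled
contig; a protein is typically covered by about three contigs because de
novo assembly fragments transcripts.

## Synthetic-data generator

Counts follow `K_gs ~ NB(μ_gs, φ)` with `Var = μ + φμ²` and

```
μ_gs = (l_g / 10³) · (N_s / 10⁶) · b_g · e_i · F_gs
```

where `l_g` is the contig's effective length, `N_s` a nominal per-sample
depth, `b_g` a per-contig base expression (per kb per million), `e_i` a
log-normal per-individual offset shared by that individual's paired
samples, and `F_gs = effect_fc` for planted IEG contigs in activated
samples, 1 otherwise. `φ = 0` degenerates to Poisson. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `n_proteins` / `frac_ieg` / `effect_fc` | 200 / 0.25 / 3.0 | recovery-experiment scale: a few hundred proteins with a quarter planted at a 3× activation effect |
| `contigs_per_protein` | uniform 1–5 | mean ≈ 3 contigs per protein, the fragmentation level of the real assembly |
| `n_individuals_per_experiment` | 6 | the study design |
| `dispersion` φ | 0.1 | typical bulk RNA-seq biological overdispersion (BCV ≈ 0.32) |
| `base_mean_log_range` | log10 ∈ (0, 2) | two decades of expression, giving per-sample means of ~2–300 counts after length/depth scaling |
| `individual_sd` | 0.2 | reproduces by-individual sample clustering without modeling hemispheres |
| `lib_size_range` | 1–3 M | moderate depth variation; real libraries vary more, but the quantile-free pseudo-count rescaling used by the exact test is accurate in this regime (see limitations) |
| `frac_consistent_homology` | 0.8 | matches the ~79–81% consistent-annotation rate observed on real data |

Hit tables: every non-orphan contig receives a valid best BLASTX hit
(e-value log-uniform in [1e-180, 1e-6]) to its protein's ortholog in each
of the five species (Bg, Ac, Ce, Dm, Tr) plus an invalid decoy row;
orphan contigs only get hits above the 1e-5 validity threshold. Only the
ordering of e-values relative to 1e-5 matters downstream. For proteins
planted as homology-inconsistent, the first species' best hit is redirected
to a decoy protein with no BLASTP support, which defeats every possible
anchor. BLASTP tables contain mutual ortholog records for consistent
proteins in all ordered species pairs.

Not emulated: read-level data (FASTQ), assembly and alignment artifacts,
multi-mapping ambiguity, GC- or length-dependent biases, partially
overlapping homology (a contig hitting paralogs of different families), and
correlated expression between contigs of the same protein beyond the shared
mean structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to assembly or
mapping artifacts in real data.

## Differential expression

The caller is a re-specification of the classic exact-test workflow, not a
bit-exact edgeR replication:

1. Per experiment, contigs with total count > 10 across the 12 samples are
   "expressed" (strict inequality).
2. TMM factors on the expressed counts. The recipe is the original trimmed
   mean of M-values: reference = sample whose 75th-percentile count
   fraction is closest to the mean; M and A on double-positive contigs;
   30%/5% two-sided rank trimming on M and A; inverse-delta-method-variance
   weights; factors recentered to geometric mean 1. Agreement with
   edgeR's `calcNormFactors` is ~1e-6 relative (asserted in a test through
   `Rscript`).
3. Counts are rescaled to the geometric-mean effective library size
   ("pseudo-counts").
4. Dispersion: the common φ solves the within-group Pearson moment equation
   `Σ (x − μ̂)² / (μ̂ + φμ̂²) = Σ_g (n_g − n_groups)`; per-contig
   method-of-moments estimates (floored at 0) are shrunk toward it as
   `0.85·φ_common + 0.15·φ_g`. The heavy fixed weight reflects that a
   6-vs-6 per-contig estimate is extremely noisy; the moment equation over
   ~10⁴ contigs recovers a planted φ = 0.1 to three digits.
5. Exact test: conditional on a contig's pseudo-count total `t = a + b`,
   group totals are `NB(n_A μ, n_A/φ)` and `NB(n_B μ, n_B/φ)` with
   `μ = t/(n_A+n_B)`; the two-sided p sums `P(split)` over all splits with
   probability ≤ the observed one (φ = 0 → conditional binomial).
6. BH step-up FDR (statsmodels); DE ⇔ FDR < 0.05 and |log2FC| > 1, logFC
   from TMM-normalized group means with a 0.5 pseudo-count per group.

Measured behavior (recomputed by the test suite and acceptance script):
type-I error at α = 0.05 on a 10,000-contig null is ≈ 0.046, inside the
99% binomial CI; with planted 3× effects the full criterion reaches ~85%
contig-level sensitivity at an empirical false-discovery proportion ≈ 2%.

**Known limitation.** Rescaling counts to a common library size changes the
Poisson part of the variance (a scaled NB is not NB), so p-values for
high-count contigs run slightly liberal when depths vary widely — this is
the problem edgeR's quantile adjustment solves and this package does not.
Under BH alone the null false-call proportion among q < 0.05 calls can
exceed the nominal rate at high counts; the published criterion's
fold-change gate removes these small-logFC calls, and the final DE
criterion is well behaved (above). The contig-level power test conditions
on informatively expressed contigs (mean ≳ 15 counts/sample): at a handful
of counts per replicate no six-replicate test can certify a 3× change,
whatever the implementation.

## Cross-experiment statistics

Overlap of the two DE sets: upper-tail `P(X ≥ k)`,
`X ~ Hypergeom(N, |A|, |B|)`, with the background `N` defaulting to the
first experiment's expressed-set size (both backgrounds are exposed, since
either is defensible). Direction concordance: fractions up-in-both /
down-in-both over the DE union, and a χ² test without Yates correction on
the 2×2 table of logFC signs, excluding exact zeros (the table construction
is not uniquely determined by the published marginals; this is the plainest
reading).

## Annotation

Best hit per contig per species = lowest e-value among valid (< 1e-5)
alignments, ties broken by higher bitscore then lexicographic subject id —
deterministic under row shuffling. Homology = membership in the top-5 valid
BLASTP alignments, symmetrized with OR over the two directions (the
BLASTP direction is not fixed by the published description; AND is
available as `symmetric=False`). Consistency uses the anchor rule — some
hit species' protein homologous to all other hit species' best proteins —
with an all-pairs mode as a flag. When several anchors qualify the
representative protein label follows the preference Ac > Bg > Dm > Ce > Tr
(best-annotated proteomes first). Single-species contigs form their own
category and get no consistency call.

## IEG calling

Directions per contig: `both` mode requires the same logFC sign in both
experiments; `either` mode takes the sign where the contig is expressed and
returns none on conflict. logFC exactly 0 counts in the denominator but in
neither direction. A protein passes at ≥ 80% (inclusive — "no less than
80%") of all its mapped contigs, DE and non-DE. Candidates additionally
need ≥ 1 DE contig and the passing direction to be upward.

Permutation null: per iteration, each protein draws its own contig count
uniformly **without replacement** from the expressed-contig direction pool,
independently across proteins; the pass percentage is recomputed and
`p = (r+1)/(B+1)` with B = 1000 by default (so the smallest attainable p is
1/1001, matching reported bounds like p < 0.001 at r = 0). Sampling with
replacement and pool restriction to annotated contigs are the two
unstatable alternatives; without replacement over all expressed contigs is
the most literal reading and both choices are arguments.

The planted-recovery experiment (200 proteins, 25% IEGs at 3×,
fragmentation 1–5) is run with `frac_consistent_homology = 1`: it measures
the DE → consistency → permutation chain, and proteins planted as
homology-inconsistent are unrecoverable by construction. The annotation
consistency rate itself is validated separately by the 0.8-fraction
generator round-trip.

## Probe design and validation statistics

Probe windows must contain the exon junction with ≥ 10 nt on each side,
length within 45–55 nt and GC within 40–50% (inclusive); ranking prefers
GC closest to 45%, then length closest to 50 nt, then the leftmost start.
Both orientations are reported (sense window and its reverse complement)
since probe strandedness is an application choice; the junction coordinate
is an input, as locating it requires an external genome alignment.

2^−ΔΔCt: `ΔCt = Ct_target − mean(reference Cts)` (the arithmetic mean of
Cts is the geometric mean on the expression scale), `ΔΔCt` relative to the
calibrator-group mean. Samples missing target or all reference Cts are
dropped with a warning.

Mann–Whitney: `U = #{x_i > y_j} + ½·ties`; the exact p enumerates all
`C(n1+n2, n1)` assignments of the pooled observed values (valid under
ties), up to 200,000 assignments (`C(20,10) = 184,756`, covering every
group size used here); beyond that, normal approximation with tie
correction. The GC denominator for probe/assembly metrics excludes
ambiguity codes. ORF percentage is the longest run of non-stop codons
(TAA/TAG/TGA, standard code, no ATG requirement) over all six frames — a
frame-openness metric, not gene calling. Bonferroni for the behavioral
latency comparisons uses m = 2, the number of pairwise comparisons
performed; the one-sided direction (trained latency greater) follows the
aversive-training prediction.

## Problem sizes and determinism

Simulation-backed checks use 10,000 contigs (null calibration), 200
proteins / ~600 contigs (recovery), and B = 1000 permutations; each is
seeded, and `scripts/acceptance.py` derives independent sub-seeds from a
single `--seed` via `numpy.random.SeedSequence`, so all reported numbers
are exactly reproducible. All printed-value statistics (probe metrics,
overlap p-values, rank tests) are deterministic closed forms or exact
enumerations.
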