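# Methods

## Scope and data model

The package analyses quantification-cycle (Cq) tables for a panel of
candidate reference genes measured across samples.  Two container states
exist: replicate-level (one row per well, carrying plate and well ids) and
collapsed (one mean Cq per gene × sample).  Sample metadata carries
tissue (`embryo | head | forelimb`), gestational age in days, litter, cDNA
batch, and a calibrator flag.  Missing Cq values are tracked explicitly;
all stability analyses run on the complete-case gene × sample submatrix,
after excluding genes missing in more than 20% of the subset's samples
(warned, configurable).

## Pre-processing

**Between-plate calibration.**  For plate *p* and a reference plate (the
lexicographically first unless specified), the offset is the mean over
shared (calibrator sample, gene) pairs of `Cq_p − Cq_ref`, pooled across
genes by default; a per-gene variant is available behind a flag.  Offsets
are additive on the Cq scale and subtracted from every well of the plate;
the operation is idempotent.  Pooling was chosen because plate effects in
practice are dominated by instrument/threshold shifts common to all
assays; the per-gene flag covers assay-specific plate effects.

**Replicate collapsing.**  Wells are averaged per (gene, sample); the
replicate SD (n−1) is recorded, singleton wells get SD 0 with a note, and
cells with SD > 0.5 cycles are flagged, never dropped.  The 0.5-cycle
default marks pipetting-level discordance without discarding data.

**Linearisation.**  `RQ[g,s] = E_g^(min_s' Cq[g,s'] − Cq[g,s])` with
per-gene amplification efficiency `E ∈ [1.6, 2.1]`, default 2.0 (perfect
doubling; primer efficiencies near 100% make the correction second-order).
Calibrating each gene to its own minimum Cq bounds RQ in (0, 1] and
cancels in every ratio-based statistic, so the choice of calibrator sample
is inconsequential downstream.

## Stability methods

All formulas use the sample standard deviation (n−1) and log base 2
throughout; the base rescales all scores uniformly and cannot change
ranks.

**geNorm.**  `V_jk = SD_s(log2(RQ_j/RQ_k))`, `M_j = mean_{k≠j} V_jk`.
Iterative exclusion removes the highest-M gene (ties broken by removing
the lexicographically greatest name, recorded in the result) and
recomputes M until two genes — the best pair — remain, sharing the final
M (their mutual V).  Both full-panel M and M-at-removal are reported,
since the one-number-per-gene summary is ambiguous for an iterative
algorithm; the consensus uses M-at-removal, for which "both best-pair
genes share one score" is well defined (full-panel M available behind a
flag).  The V(n/n+1) curve takes the per-sample geometric mean of the
top-n genes' RQs as the n-gene normalization factor and reports
`SD_s(log2(NF_n/NF_{n+1}))` for n = 2..k−1.

**deltaCt.**  `score_j = mean_{k≠j} SD_s(Cq_j − Cq_k)` on collapsed mean
Cq.  With E = 2 for all genes this equals geNorm's M exactly, because
`log2(RQ_j/RQ_k) = (Cq_k − Cq_j) + const`; the test suite uses this
identity (and an independent brute-force Cq-difference implementation) as
a cross-method oracle at 1e−9.

**BestKeeper.**  The index is the per-sample geometric mean of all
genes' Cq values (the method's original formulation; an arithmetic-mean
variant sits behind a flag).  Genes are ranked by Pearson *r* against the
index; per-gene Cq SD and CV (% of mean Cq) are reported as descriptors.
A zero-variance gene has no defined correlation and is assigned r = 0
with a recorded warning — note the structural caveat that an r-based
ranking penalises perfectly constant genes; this is inherited from the
method, documented rather than repaired.  Complete-case samples only;
dropped samples are listed.

**NormFinder.**  On `y = log2(RQ)` under the heteroscedastic two-way
model `y_gs = α_g + β_s + ε_gs`: after double-centering, the naive
per-gene residual variance `s²_g = Σ_s r²_gs/(n−1)` is contaminated by the
other genes' noise through the per-sample mean, and the closed-form
bias-corrected estimator is

    σ̂²_g = (k/(k−2)) · (s²_g − mean(s²)/(k−1)),  floored at 0.

Ungrouped stability is `√σ̂²_g`.  Mean-unbiasedness of σ̂² was verified by
simulation (mean ratio to truth 0.998–1.003 over 20 000 replicates at
k=8, n=20).  Note that the *median* of any variance estimate at ~19
degrees of freedom sits ~4% below its mean (χ² skew); calibration checks
therefore assert mean-unbiasedness sharply and the median only loosely.
Grouped mode applies the same estimator within each group, computes
intergroup deviations `d_gj` of the sample-centred group mean from the
grand mean (these sum to zero over genes within each group), shrinks them
by `γ̂²/(γ̂² + σ̂²/n_g)` with `γ̂²` the across-gene variance of d in the
group, and scores `mean_g(|d̃| + √(σ̂²/n_g))`.  The best pair minimises
the same expression for the two-gene average, searched exhaustively.
Exact constants differ across published ports of the method; the formulas
above are fixed here and validated by parameter recovery rather than by
matching any one port bit-for-bit.  k < 3 is rejected (the correction is
undefined).

**Consensus.**  Per-gene geometric mean of geNorm M-at-removal, deltaCt
score, inverted BestKeeper correlation `1 − max(r, 0)` (negative
correlations are first set to zero, giving the worst score 1), and
ungrouped NormFinder stability.  Scores are floored at ε = 1e−6 so a
single exactly-zero method cannot collapse the product; ε is configurable
and irrelevant on real data.  Genes are ranked ascending.

## Priming QC

Random priming is required to reverse-transcribe non-polyadenylated RNAs
(rRNA) and the 5′ ends of long transcripts, so a cDNA batch with failed
random priming shows late Cqs for such sentinel genes only.  Per batch,
the detector computes the median (over sentinel genes) of the batch's
median Cq minus the global median Cq, and the same contrast for the
non-sentinel panel.  A batch is flagged when the sentinel deviation
exceeds the panel deviation by ≥ 1.5 cycles; flagging on the difference
makes the decision exactly invariant to uniform batch shifts, which are
quality effects rather than priming failures.  Batches whose panel-wide
shift exceeds 0.5 cycles are annotated separately as global shifts.
Medians resist single-sample outliers.  The 1.5 / 0.5-cycle defaults flag
a ~3-cycle rRNA defect with ample margin; both are configurable.
Long-transcript secondary sentinels (e.g. a 5′-anchored dystrophin dp71
assay) can be added to the sentinel list; no transcript-length model is
implemented.  Detection only — no correction is attempted, since the
remedy is fresh cDNA.

## Synthetic data generator

The generator emulates a 44-sample embryonic study: whole embryos
n = {3,3,4,3,3,3,5} at E{11.5..16.5, 18.5} (24), heads {3,3,5} and
forelimbs {3,3,3} at E{13.5, 16.5, 18.5} (11 and 9).  Wells are
triplicate by default, samples round-robin across 3 plates with
N(0, 0.3²) plate offsets, three calibrator samples run on every plate,
and four cDNA batches.  The well-level model is

    Cq = baseline − slope_tissue·(age − 14.5) + c·u_s + q_s
         + plate + Δ_batch·[priming-sensitive] + N(0, σ_g²) + N(0, σ_tech²)

with q_s ~ N(0, 0.5²) a per-sample quality effect, σ_tech = 0.15, u_s a
per-sample latent trajectory (standardized to zero mean / unit variance
per dataset, the loadings carrying its scale), and age 14.5 the design
midpoint so baselines are mid-gestation expectations.  Litters are
assigned per (tissue, age) block; a litter effect exists but defaults to
off.  The priming artifact adds +3 cycles to priming-sensitive genes in
one designated batch.

The default 15-gene panel mirrors the archetypes such a study meets: six
trend-free housekeeping genes (σ_g 0.27–0.30), two noisy classics
(SDHA, GAPDH), two age-upregulated genes (HPRT1 +0.25, B2M +0.30
log2/day), two tissue-conditional genes whose trend direction depends on
tissue (CYC1, EIF4A), a co-regulated pair with a mild shared decrease
(CDC40, HTATSF1, −0.02 log2/day) and an abundant priming-sensitive rRNA
(18S).  The latent axis models differential sensitivity to RNA
quality/composition: the housekeeping cluster loads 0.65 cycles per unit,
the co-regulated pair 0.95, developmentally-driven genes 0.40, rRNA and
the noisy genes 0.  This loading structure is what reproduces the
characteristic method disagreement for co-regulated genes: pairwise-ratio
methods (geNorm) see two genes that track each other almost perfectly,
while variance-based methods (deltaCt, NormFinder) see two genes that
deviate from the panel consensus.  Loadings and noise tiers were fixed by
a one-off design simulation choosing values for which that qualitative
behaviour holds for the large majority of seeds; raw Cq SDs land around
0.9–1.1 cycles per gene, in the range typical of embryonic panels.  The
margins are genuinely finite: because deltaCt and geNorm M are the same
statistic up to a single mutual-variation term, the joint ordering
(geNorm keeps the pair, deltaCt/NormFinder demote it below every stable
gene) holds in roughly 9 of 10 datasets, not all.

Every realized effect (q, u, plate, batch, litter offsets, slopes, seeds)
is stored in `SyntheticTruth`, which can reconstruct the noise-free Cq
surface exactly; recovery tests compare estimates against it.  What the
generator does **not** emulate: amplification-curve shape and Cq calling,
efficiency drift, melt behaviour, litter-specific biology (off by
default), and the correlated biological noise structure of real
co-expression networks beyond a single latent axis.  Passing tests
therefore demonstrate algorithmic correctness and qualitative behaviour
under a plausible noise model, not performance guarantees on any real
dataset.

## Normalization and validation

NF_s is the geometric mean over reference genes of RQ (exact pass-through
for a single reference, keeping self-normalization exactly 1); RQs are
linear, so normalization is division.  Validation computes the per-tissue
summed per-timepoint CoV (SD/mean per timepoint, ≥2 samples required,
summed over the tissue's timepoints) before and after normalization, and
compares NFs built from different reference subsets by Pearson r and OLS
gradient with free intercept (a through-origin variant is available).
Per-tissue computation matches how developmental panels are read; the
overall figure is the per-gene sum across tissues.

## Numerical choices and degenerate inputs

- Sample SD with n−1 everywhere; singleton replicate SD defined as 0 with
  a note.
- geNorm/deltaCt need ≥3 genes and ≥3 complete samples; NormFinder
  additionally k ≥ 3 for the bias correction and group sizes ≥ 2.
- geNorm M ties broken deterministically (remove the lexicographically
  greatest name) and recorded; ties are measure-zero on real data.
- Out-of-range Cq rows (outside (0, 45)) are rejected with row-indexed
  diagnostics; literal NA tokens become missing cells.
- Efficiencies outside [1.6, 2.1] are rejected.
- Zero-variance genes in BestKeeper score r = 0 with a warning.

## Known limitations

- BestKeeper's regression p-values and iterative index refinement are out
  of scope; ranking is by r only.
- No confidence intervals on stability values; closed-form estimators
  only, no numerical mixed-model fitting.
- Grouped NormFinder constants follow one fixed, parameter-recovery-
  validated convention; other ports may differ by a constant factor, so
  cross-software comparisons should be made on ranks.
- The deposited-workbook reader is generic .xlsx support for the long and
  wide schemas, not a bespoke mapping of any particular workbook layout.
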