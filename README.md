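# refstab

Reference-gene stability analysis for RT-qPCR, built for developmental /
multi-tissue panels where no gene can be assumed stable a priori.

Candidate reference genes are scored by four established algorithms and an
integrated consensus:

- **geNorm** — pairwise variation `V_jk = SD(log2(RQ_j / RQ_k))`, gene
  stability `M_j = mean_k V_jk`, iterative exclusion of the worst gene down
  to a "best pair", and the `V(n/n+1)` curve that gauges the benefit of an
  (n+1)-th reference.
- **deltaCt** — mean over partner genes of the SD of pairwise Cq
  differences (on mean Cq values; with perfect doubling it is algebraically
  identical to geNorm's M, which the test suite exploits as an oracle).
- **BestKeeper** — per-sample consensus index (geometric mean of panel
  Cqs); genes ranked by Pearson correlation *r* with the index.
- **NormFinder** — model-based variance decomposition on `log2(RQ)` with a
  closed-form bias-corrected per-gene variance; grouped mode adds shrunken
  intergroup deviations and an opposite-bias best pair.
- **Consensus** — per-gene geometric mean of the four scores (geNorm
  M-at-removal with the best pair sharing the final M; BestKeeper *r*
  inverted as `1 - max(r, 0)`), ranked ascending.

Around the ranking sit the practical stages of a qPCR study:
between-plate calibration via shared calibrator samples, replicate
collapsing with discordance flags, linearisation
`RQ = E^(Cq_min - Cq)`, normalization-factor (NF) construction and
validation (summed per-timepoint CoV, NF-vs-NF agreement), QC that detects
cDNA batches with failed random priming from rRNA sentinels, and a
synthetic data generator that emulates a 44-sample embryonic time-course
(24 whole embryos E11.5–E18.5, 11 heads, 9 forelimbs, 15 genes) with full
ground truth, so every stage is testable end to end.

## Worked example

```python
from refstab import rank_subset, simulate

table, truth = simulate(seed=1)       # replicate-level wells + ground truth
res = rank_subset(table, subset="all")  # calibrate, collapse, rank
print(res.consensus.table().round(3))
```

prints (abridged):

```
         genorm  deltact  bestkeeper  normfinder  consensus  rank
PAK1IP1   0.378    0.594       0.067       0.213      0.238     1
CDC40     0.190    0.704       0.080       0.510      0.272     2
RPL13A    0.372    0.609       0.085       0.288      0.273     3
...
B2M       0.830    0.898       0.334       0.720      0.651    14
18S       1.632    1.632       0.749       1.563      1.329    15
```

Reading it: the trend-free housekeeping genes (PAK1IP1, RPL13A, ...) hold
the top consensus ranks while the age-regulated genes (HPRT1, B2M) and the
priming-damaged rRNA (18S) sink to the bottom.  The co-regulated pair
CDC40/HTATSF1 shows the classic method disagreement: it is the geNorm best
pair (shared M = 0.190 — the two genes track each other almost perfectly)
yet both members score worse than every stable gene under deltaCt and
NormFinder, because their shared trajectory is variation like any other to
a variance-based method.  That disagreement is the signature of
co-regulation, not of stability.

The `examples/` directory holds one short script per capability
(simulation + priming QC, ranking, grouped NormFinder, NF validation);
each prints its numbers with a line on what they mean.  A thin CLI mirrors
the same stages:

```
refstab simulate --seed 1 --out run/
refstab qc run/cq_long.csv --out run/
refstab rank run/cq_long.csv --subset embryo --groups age_days --out run/
refstab validate run/cq_long.csv --ref ACTB --ref RPL13A --ref AP3D1 \
    --target HPRT1 --target B2M --out run/
```

## Input formats

Long CSV/TSV (one row per well: `sample_id, gene, cq` plus optional
`plate, well, tissue, age_days, litter, cdna_batch, is_calibrator`), wide
CSV (gene × sample matrix with a separate metadata file), or `.xlsx` in
either layout.  See `refstab.io.read_cq`.

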