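# Methods

This note documents the models behind `ffenrich`: what the synthetic data
emulate, how each analysis stage is defined, the defaults that matter, and
what the simulations can and cannot say about real clinical data.

## Synthetic cfDNA model

Each simulated sample is a set of independent aligned fragments. A fragment
is fetal with probability equal to the sample's fetal fraction; its length
is drawn from the origin-specific size distribution; its genomic bin is
drawn with probability proportional to *bin span × chromosome copy weight ×
GC-bias curve*; its start is uniform within the bin. Coordinates are
0-based, half-open.

**Genome.** `GenomeModel.scaled_hg19()` uses hg19 chromosome lengths
divided by 1000 with 20-kb bins (~166 bins). This preserves the relative
chromosome shares the z-statistic depends on while keeping million-fragment
cohorts cheap. Per-bin GC is a smoothed, seeded random field with mean
0.50 clipped to [0.36, 0.64]; because most bins sit above the bias optimum
(below), the injected quadratic bias is effectively monotone in GC over the
observed range, as it is in real binned data.

**Size distributions** (integer support 50–250 bp):

* maternal: `0.80·N(166, 9) + 0.16·N(143, 9) + 0.04·U[100, 200)`
* fetal:    `0.42·N(160, 9) + 0.29·N(143, 9) + 0.24·N(137, 11) + 0.05·U[100, 200)`

The maternal mixture is the classical chromatosome (166 bp) peak with a
minor mono-nucleosome (143 bp) component. The fetal mixture depletes and
shifts the chromatosome peak down a few bases and adds a broad sub-150
shoulder. The exact parametric forms are free modelling choices — no
published parametric form exists — and were fixed once, analytically, so
that the fetal/maternal density ratio across the ten 10-bp bins rises from
[100,110) to a peak in [120,130) and falls below 1 from 160 bp on, and so
that the sub-160 mass ratio is ≈ 2.0. These are the qualitative features
(unimodal fold-change profile; roughly two-fold FF gain from a <160 bp
cut) that length-based enrichment rests on. Note that merely down-weighting
a fixed 166 bp fetal peak cannot produce enrichment in the [150,160) bin;
the peak itself must shift.

**chrY content.** A male fetus places fragments on chrY in proportion to
chrY's share of a 46,XY genome (sex chromosomes at half weight); a female
fetus emits none. Maternal fragments reach chrY only through a mismapping
weight (default 0.01 × chrY length), giving a female-pregnancy chrY read
fraction of ~2×10⁻⁴ — the baseline attainable with strict unique-mapping
filters. A trisomic chromosome carries 1.5× fetal weight (three copies
versus two), which elevates the expected chromosome ratio by `(1 + ff/2)`.

**GC bias** is `max(0.05, 1 − a·(gc − 0.40)²)` with per-sample amplitude
`a ~ N(4.0, 0.8)` in cohorts, emulating run-to-run bias variation the
correction stage must absorb.

**Duplicates / multi-mappers.** 2% of records are re-emitted copies of
existing records (flagged duplicate); 1% are flagged non-unique. Natural
coordinate collisions also occur and are deduplicated like PCR duplicates,
exactly as coordinate-based duplicate marking does on real single-end data.

**Cohort defaults** mirror the screening population: FF ~ N(0.13, 0.045)
truncated to [0.03, 0.30], even sex ratio, 3.5 million fragments per
sample (the platform read count).

## Analysis stages

**Read filters** (in order): drop length < 50 bp; drop non-unique mappers;
drop duplicates — any pre-flagged record, then every repeat of a
(chrom, start, length) key. Flagged records are removed *before* the
first-occurrence scan so the retained count is permutation-invariant.

**Size selection**: strictly `length < cutoff` (default 160 bp). The bead
simulator instead keeps each fragment with probability
`1/(1 + exp(k(L − 160)))`; presets 1.2×/1.3×/1.5× use k = 0.15/0.30/0.60,
the steepest preset approaching the hard cutoff.

**Fold-change table**: reads are split into the ten bins [100,110) …
[190,200); the chrY read fraction per bin is divided by the pooled chrY
fraction of *all* reads (reads outside 100–200 bp stay in the denominator).
Samples are pooled into mixed sets (default 100 samples) and set-level
fractions averaged; empty bins report a missing fold change, never zero.

**GC correction**, three steps, each preserving the unmasked total to
1e-6 relative: (1) per sample, loess (span 0.75, degree 2 — the classical
defaults; implemented as a tricube local-quadratic smoother) of raw count
on GC, fit on unmasked *autosomal* bins and evaluated everywhere, with
counts rescaled by `median/fitted`; (2) intra-run normalization — divide
each bin by the across-run median of its depth-normalized step-1 value
(requires ≥ 8 run samples, otherwise skipped and flagged); (3) regression
of the result on GC and GC², subtracting the fitted component and flooring
at 0. Masked bins — GC outside [0.2, 0.8], non-positive loess fit, zero
run median, or partial end-of-chromosome bins (span differences would
masquerade as depth) — are excluded from all fits and ratios. Sex
chromosomes are excluded from the fit domain because their depth encodes
copy number, not GC. The intra-run step is defined per bin (per-bin
medians); the alternative reading (component-wise normalization) is not
recoverable from the three-step description and the per-bin form is the
standard one.

**Calling**: ratio = corrected counts on the chromosome's unmasked bins /
all unmasked autosomal bins. Reference mean and SD (n−1) come from ≥ 20
euploid samples processed with the *same* protocol — enriched libraries are
scored against an enriched reference, since size selection shifts every
chromosome ratio slightly. Decision: no-call when unique reads fall below
the scaled 3.5M-equivalent floor, when the FF estimate is unpredictable, or
when FF < 4%; otherwise positive for any tested chromosome (13/18/21) with
z strictly > 3.

**Fetal fraction.** chrY method: `FF = (y − b_f)/(y_m − b_f)` clamped to
[0, 1]; `b_f` (zero-fetal baseline) and `y_m` (pure-male chrY fraction) are
the intercept and intercept+slope of a regression of chrY fraction on known
FF in a calibration cohort — the female-cohort mean is only a consistency
check, because it is diluted by the maternal share. Size method: loess
curves (span 0.75) map the read shares of regions A = [130,140) and
B = [155,175) bp to FF, trained on chrY-labelled male-fetus samples; the
curves are stored as knots + fitted values and evaluated by interpolation,
clamped at the training range. The discrepancy
`P_diff = (P_A − P_B)·2/(P_A + P_B)` is stored signed, as defined, but the
unpredictability rule uses |P_diff| > 0.40 — a signed rule could never flag
P_B ≫ P_A. The boundary 0.40 itself is predictable (strict >).

**Complexity.** `complexity = Σ unique SNP-covering reads / panel size`
(default 300 SNPs). The duplication simulation draws
`n = d·genome/150` reads with replacement from `M = C·genome/150` abstract
molecules; the closed form `1 − M(1 − (1 − 1/M)^n)/n ≈ d/(2C)` is
genome-size-independent in the shallow regime, so the scan runs on the
scaled genome. Under the default 2% duplication ceiling ("low duplication
rate") the 0.1× scan first passes at C = 3 on the default grid
(d/2C crosses 2% between C = 2 and C = 3), the minimum-complexity
threshold. The ceiling itself is a calibration choice; the grid and ceiling
are configurable.

**Performance.** Wilson score intervals (statsmodels) for all proportion
metrics; no-calls are failures, excluded from every metric denominator;
specificity uses true negatives over condition negatives and NPV true
negatives over called negatives — the only reading consistent with the
published table arithmetic. The 2×2 rate comparison uses Pearson χ²
*without* continuity correction (the corrected statistic would not reach
p ≤ 0.01 on the failure-rate contrast) or Fisher's exact test when an
expected cell is below 5. Percentages are reported half-up at 2 decimals.

## Problem sizes

Simulated experiments use the 1/1000-scale genome. Read counts per sample:
3.5 million (the platform count) for the rescue experiment, where z-power
at post-enrichment FF ≈ 6–7% requires it; 0.5–1.2 million for fold-change,
enrichment-gain and calling-calibration experiments; 0.15–0.2 million for
FF-estimator cohorts, where chrY counting power suffices. The rescue
experiment simulates trisomy-21 samples at FF = 3.3%: below the 4% floor
before enrichment (hence no-call), ~6.5% after, with 20 replicates scored
against a 25-sample reference per protocol.

## What the simulations do and do not show

The generator reproduces the statistical structure the method depends on —
two overlapping size distributions with a shorter fetal component, linear
chrY–FF relation, smooth GC bias, Poisson-level count noise, trisomy
dosage — so passing tests demonstrate the pipeline's internal consistency
and parameter recovery under those assumptions. Real cfDNA adds features
the model omits: 10-bp sawtooth periodicity below 150 bp, mappability and
copy-number artifacts, per-sample size-distribution variation (so real
region-ratio–FF curves are noisier than the simulated ones),
gestational-age and maternal-BMI effects on FF, confined placental
mosaicism (a real source of post-enrichment false positives), and true
fetal mosaicism (unrescuable false negatives). Clinical descriptive
quantities from the undeposited cohorts (mean FF 11.3%→22.6%, per-bin fold
changes up to 2.64, measured library complexities) are therefore treated as
qualitative shape targets, not numbers to reproduce; in this clean
simulation the rescue mechanism operates mostly through the FF floor
(no-call → positive), whereas real false negatives also involve z-noise
from biological variation. The σ of reference chromosome ratios here is
Poisson-limited, i.e. smaller than in real cohorts; absolute z values are
correspondingly larger.

## Numerical choices

Loess: tricube weights over the nearest `ceil(span·n)` points, local
quadratic, evaluated exactly at the query point; degenerate windows reduce
the polynomial degree. Dedup keys pack (chrom, start, length) into one
int64. RNG: a single integer seed per sample; cohorts derive per-sample
seeds via `SeedSequence.spawn`, so cohorts are bit-reproducible and
samples statistically independent. Fragment starts are clamped so
`start + length ≤ chromosome length`. Ratios and references raise on zero
denominators and zero SDs rather than returning sentinel values.
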