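# Methods

This note documents the models and algorithms behind `cytobench`, the
defaults that matter, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

An FCS file contributes an events × channels matrix; merging downsamples
every annotated file to the same event count (correcting for imbalanced
cell numbers) and stacks the shared channels, keeping a per-event sample
index and the acquisition Time column. Time is carried separately from the
analysis channels: it is never transformed or normalized, but signal
cleaning always has access to it, regardless of marker selection. FCS
reading supports versions 2.0–3.1, list mode, integer and float data
(the analysis segment is ignored; `$PnE` log-amplification scaling is not
applied — files from the supported repositories store linear data). Writing
produces FCS 3.1 float32 with UTF-8 text. Marker names prefer `$PnS` with
`$PnN` fallback; comparisons are case-sensitive after whitespace trim. The
Time channel is the first channel whose name case-insensitively equals
"Time"; its absence only disables signal cleaning.

Downsampling strategies: `uniform_random` (default; without replacement,
seed required), `density_preserving` (weights ∝ inverse of a per-channel
histogram density estimate, so rare regions survive), `take_first`.

## The 25 methods

**Compensation** (observed x = true y · S, S unit-diagonal): `FLC`/`CMP`
invert S directly; `CTS` solves per-event non-negative least squares
y = argmin_{y≥0} ‖x − yS‖₂ (suited to mass cytometry, where abundances are
non-negative; the unconstrained solution is used where already feasible);
`MTC` subtracts a per-file autofluorescence background (1st percentile per
channel) before inverting; `ATS` re-estimates S from single-stain control
files by iteratively reweighted Huber regressions of each channel on the
stained channel (4·MAD inlier trimming, 3 rounds) and falls back to direct
inversion with a logged warning when controls are absent. S comes from an
argument, a CSV (header = channel names, square body), or the `$SPILLOVER`
keyword.

**Transformations** (monotone, per channel; Time excluded):

| id | map | defaults |
|---|---|---|
| ACS | asinh(x/c) | c = 5 (MC), 150 (FC) |
| ANN | asinh, automatic cofactor | c = max(1, 5th pct of positive values) |
| ARN | asinh (as ACS) then min–max to [0,1] | |
| BEP | inverse of a·e^{by} − c·e^{−dy} + f by bisection | a=c=0.5, b=d=1, f=0, tol 1e−8 |
| BOX | Box-Cox (x−min+1)^λ, λ by MLE | λ fit on ≤ 1000 evenly spaced order statistics |
| FVS | asinh, cofactor minimizing Bartlett's statistic over 5 deterministic 1-D k-means bins | 16-point log grid 10⁻¹…10⁴ |
| HPL | sign(x)·log10(1 + |x|/T) | T = 100 (FC), 1 (MC) |
| LGT | four-parameter logicle | T=262144, W=0.5, M=4.5, A=0; safeguarded Newton, rel. tol 1e−8; returns the [0, M] decade axis |
| LIN | affine rescale | to [0, 4.5] |
| LNT / LOG | ln / log10 of (x − min + 1) | |
| QUA | midrank → Φ⁻¹(r/(n+1)) | |
| SCA | z-score (SD = 0 → zeros) | |
| TRU | max(x, t) | t = 1 |

With BEP's defaults the forward map is exactly sinh, so its inverse equals
asinh — a convenient closed-form cross-check of the bisection code. All
data-driven fits (BOX, FVS) use deterministic evenly spaced subsamples, so
every transformation is seed-free and reproducible.

**Normalization** (≥ 2 samples; per channel; all per-sample maps monotone
piecewise-linear): `GSN` estimates each sample's kernel density (512-point
grid, Scott bandwidth), keeps up to 2 modes carrying ≥ 25% of the maximum
peak density, truncates to the common mode count by density and matches
modes by location, then warps each sample so its modes land on the
cross-sample mean locations. `WPS` maps each sample's deciles onto the
cross-sample mean deciles. `FDN` does the same on a dense 101-point
percentile grid — effectively classic quantile normalization, kept distinct
from WPS by its granularity. Samples with fewer than 50 events pass through
unchanged with a warning.

**Signal cleaning** (per file; events binned by Time into B = max(10,
n/500) equal-count bins, overridable): `FAI` flags a bin when its event
rate deviates from the across-bin median by more than k = 3 robust SDs
(MAD·1.4826, floored at 10% of the median rate — with few bins the MAD of
the rates is itself noisy, and sub-10% rate wobble is ordinary acquisition
jitter) or when any channel median sits more than k event-level robust SDs
from the file median; statistics are re-estimated once without the flagged
bins (two passes). `FCL` scores each bin by the summed squared
centred-log-ratio deviation of its composition over 5 per-channel global
intensity classes and flags runs of ≥ 2 consecutive bins above
median + 3·MAD (segments, not isolated bins). `FCU` iteratively removes the
bin with the highest mean absolute robust z over 8 summaries (mean, median,
5/20/80/95th percentiles, variance, skewness) until the worst bin scores
below 2.0. Cleaning is a pure subset operation — retained events are
bit-identical — and raises if it would remove more than
`max_removed_fraction` (default 0.5) of a file.

Workflows apply the four steps strictly in the order compensation →
transformation → normalization → signal clean; the all-`NON` workflow is
the identity.

## Evaluation

**CSI.** Clustering is k-means (k-means++, 10 restarts, fixed seed);
default k = 4 × number of conditions — enough granularity for abundance
features without starving clusters. *Accuracy*: each sample is summarized
by its cluster-abundance fractions; a leave-one-sample-out L2 logistic
regression (features standardized within the training fold, balanced class
weights so the held-out sample's class is not penalized for being the fold
minority) predicts the condition; Ca = balanced accuracy. *Tightness*:
Euclidean silhouette on a seeded subsample of ≤ 5000 events, Cb = (s̄+1)/2.
*Robustness*: 5 subsamples of 80% of events are re-clustered; Cc = mean
adjusted Rand index against the full clustering on the shared events,
clipped to [0, 1]. *Correspondence*: per marker, the effect is the
difference of condition medians standardized by the pooled SD; a known
marker is recovered when its sign matches the stated direction and its
|effect| ranks within the top max(#known, 25% of markers); Cd =
recovered / #known. Datasets without a marker list skip Cd.

**PTI.** Pseudotime: PCA to 5 components → k-means with k = 3 × number of
time points → minimum spanning tree over centroids (Euclidean) → root =
centroid richest in earliest-time-point events → per-event pseudotime =
geodesic MST distance of its centroid plus the event's projection onto the
edge toward the root (clipped to half the edge), min–max normalized. The
procedure is deterministic for a fixed seed and deliberately
dependency-light: it needs to rank *preprocessing* variants, not to win
trajectory-inference benchmarks. *Conformance*: Kendall τ-b against
ordinal collection time, mapped to [0, 1]; invariant under monotone
reparameterizations of pseudotime. *Smoothness*: per marker, events are
ordered by pseudotime and binned into 50 equal-count bins; roughness
R = Σ(μ_{b+1} − μ_b)²/Var; the "naive" baseline computes R under a seeded
random ordering of the same events; a paired one-sided t-test across
markers of R < R_naive gives Cb = 1 − p, with 0.5 by convention when all
differences are zero. (Acquisition order would be a defensible alternative
baseline; random ordering was chosen because acquisition order is itself a
quantity the workflows under test modify via signal cleaning.)
*Robustness*: pseudotime is re-inferred on paired 80% subsamples; Cc =
mean |Spearman ρ| on shared events, the absolute value absorbing the
arbitrary direction of a trajectory. *Correspondence*: each protein's peak
activation is the argmax of its 50-bin profile (ties → earliest bin); a
protein violates the hierarchy when it peaks strictly before its pathway's
key protein; Cd = 1 − violations / total proteins (per-protein counting,
matching how violation fractions are conventionally quoted).

## Ranking

Criterion values are rounded to three decimals *before* categorization and
summation. Default fixed cutoffs (superior / good):

| | Ca | Cb | Cc | Cd |
|---|---|---|---|---|
| CSI | 0.85 / 0.71 | 0.75 / 0.62 | 0.30 / 0.20 | 0.90 / 0.70 |
| PTI | 0.75 / 0.60 | 0.98 / 0.90 | 0.86 / 0.50 | 0.90 / 0.70 |

These were chosen to be interval-consistent with every published category
label available for these criteria; Cd cutoffs are conventional since no
labelled values are available. A quantile mode (90th/70th percentiles of
the evaluated cohort, per criterion) is provided for cohort-calibrated
categorization. Categories weigh 1 / 0.8 / 0.1; ranking sorts by weighted
category sum, then metric sum, then the workflow string — a total,
deterministic order invariant to input permutation.

## Parallel scanning

Each workflow is an independent end-to-end task whose seed is derived by
hashing (base seed, workflow string), so the ranked table is bit-identical
for any worker count or scheduling; failures (e.g. Box-Cox on a constant
channel) are recorded per workflow without aborting the scan.

## Synthetic data

The CSI generator draws each sample from a log-normal mixture (3
populations, per-population/channel log-means ~ U(1, 3), log-SD 0.4),
plants directional shifts on 3 markers sized at 2 × the marker's **total**
log-scale spread (within-population noise plus between-population
dispersion — the scale on which a "well-established" differential marker
separates conditions; scaling to the within-population noise alone would
let the also-planted abundance shift masquerade as a stronger marker),
doubles population 0's abundance in the second condition, mixes channels
through a distance-decaying spillover matrix (intensity 0.05), applies a
10% linear multiplicative drift over acquisition time, and optionally
injects a contiguous anomaly window (event-rate multiple plus a 3× level
shift on half the channels). FC mode adds Gaussian detector noise
(negatives occur); MC mode zero-inflates low signals. Defaults: 2
conditions × 3 samples × 1500 events over 10 channels.

The PTI generator gives each cell a latent time u uniform within its
sample's (slightly overlapping) collection window and drives each protein's
log-mean with a rise-and-fall sigmoid pulse centred at its cascade
midpoint, midpoints strictly increasing along each pathway (7 pathways, 39
proteins, log noise σ = 0.3, 4 time points × 500 events).

What passing these experiments shows: the pipeline preserves planted
condition shifts, abundance differences, anomaly windows and activation
order, and the criteria can tell structure-preserving from
structure-destroying workflows. What it does not show: performance on real
data with doublets, debris, barcoding artifacts, batch-varying panels or
heavy-tailed detector noise — none of which the generators emulate — nor
that any particular method implementation matches the behavior of the
R packages whose roles they fill.

## Numerical choices and degenerate inputs

Logicle inversion is safeguarded Newton with a bisection fallback and
brackets grown until they straddle the target; BEP bisection stops at
|g(y) − x| < 1e−8. Silhouette on all-identical points follows the library
0/0 → 0 convention; z-scoring a constant channel yields zeros; Box-Cox on
a constant channel raises. Peak ties in the 50-bin profile break toward
the earliest bin. Pseudotime is forbidden to be constant. MAD scales use
the 1.4826 normal-consistency factor; zero MADs disable the corresponding
check rather than dividing by zero.

## Known limitations

- Criterion constructions are one representative metric each; menus of
  alternative metrics per criterion are out of scope.
- k-means is the only clustering backend (pluggable in principle).
- No branching-trajectory topology: pseudotime is a single geodesic axis.
- Bootstrap robustness at small k can be optimistic on structureless data:
  a 2-way k-means split of an isotropic cloud tracks the top-variance
  direction and is itself reproducible. Comparisons against unstructured
  baselines should use larger k.
- Spectral (unmixed) cytometry, Gating-ML, bead normalization and doublet
  handling are out of scope.
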