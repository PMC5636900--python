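# Methods

This note documents the models, calibrations and numerical choices behind
`barrelpt`, and what the synthetic cohorts do and do not emulate.

## Analysis conventions

All depths are measured along one coordinate axis (default: the second),
increasing from the pia at 0 µm. The default layer bands are L1 [0, 100),
L2/3 [100, 600), L4 [600, 900), L5A [900, 1050), L5B [1050, 1400), L6
[1400, 1850) µm; only the L5A/L5B border (1050 µm) is anatomically anchored
by the analysis, the others are nominal and configurable. All time windows
are half-open `[t, t+Δ)` in ms relative to stimulus onset; a spike exactly
at 0 belongs to the evoked period. The standard recording window is
[−200, 1100) ms around a 700 ms stimulus: ongoing activity in [−200, 0),
onset response in [0, 100), sustained response in [100, 700). Evoked rates
are reported as elevations above the ongoing rate, unclamped.

### Laminar morphometry

Each dendritic segment's Euclidean length is split across layers in
proportion to the overlap of its depth interval with each band (exact for
piecewise-linear cables; verified in tests against 0.1 µm dense sampling).
A branch point is any non-soma node with ≥2 children (a trifurcation counts
once) and is assigned to the layer containing its depth. Per-layer
complexity = path length × branch points, so complexity is zero in any
layer without a bifurcation regardless of cable length. The soma node
itself contributes no dendritic length. Nodes above the pia are clipped to
depth 0 with a warning.

The feature registry holds 21 named features (soma depth; total/basal/
apical path length; total/basal/apical branch points; per-layer length and
branch points for L1–L5B; maximal horizontal tuft extent below 300 µm
depth; apical trunk length to the main bifurcation; number of primary basal
stems; maximal branch order). The registry is pluggable: the exact feature
list used for cell-type separation can be swapped without touching
downstream code. PCA z-scores columns, drops constant features with a
warning, and fixes component signs by making each component's
largest-magnitude loading positive.

### PSTH similarity

PSTHs use 5 ms bins pooled over trials (last bin closed). Normalization
follows the four-step recipe: subtract the ongoing rate bin-wise, set
negative bins to zero, divide by the maximal bin, then sum bin-wise
absolute differences over the entire window as the dissimilarity. Group
templates average the *raw* per-cell PSTHs of a group and then
baseline-subtract (by the group-mean ongoing rate) and normalize — rather
than averaging normalized per-cell PSTHs — because the group-average PSTH
is the object being normalized in the published recipe. A cell is not
excluded from its own group's template by default; a leave-one-out switch
exists for bias checks. A 0/0 similarity index is defined as 0 (neutral).

### Target classification

Clusters (default: POm, Sp5C, merged SC/Pons) carry sample means and
covariances (denominator n−1). A ridge of `1e-6 · trace(C)/DOF` is added
to the diagonal so that near-degenerate small samples remain invertible;
the trace-normalized ridge is isotropic and therefore deliberately not
scale-equivariant (exact affine invariance holds at ridge 0). When a
cluster has fewer than DOF+1 members its full covariance is rank-deficient;
such clusters fall back to a diagonal covariance of per-feature sample
variances, with a warning. Assignment is to the minimum Mahalanobis
distance (ties to the lowest cluster index, flagged); confidences use
`p_i = 1 − F(d_i², DOF)` with the chi-squared CDF, normalized across
clusters; if every `p_i` underflows to zero the assigned cluster receives
confidence 1, flagged. Dual-target cells are excluded from cluster fitting
and scored as held-out queries. Features are used on their native scales by
default (Mahalanobis distances are per-cluster scale-aware); a z-scoring
flag exists for cross-feature comparability studies.

The "dendritic" axis of the combined structure–function space is the first
principal component score of the cohort's z-scored per-layer complexity
5-vectors. This scalar reduction is a package design choice; the full
5-vector space is also available (DOF adjusts accordingly).

### Soma-density profiling

Somata are summed in 50 µm depth bins per slice. Slices are aligned by
integer-bin translation so each NeuN profile's L4 peak lands on the median
peak bin; slices whose NeuN maximum lies outside the configured L4 range
are excluded with a warning (equal-height peaks tie-break to the shallower
bin). After averaging, the amplitude scale onto the per-column reference
NeuN profile is the closed-form least-squares minimizer
`s = Σ p·ref / Σ p²`, searched over a small set of integer shifts with the
best (scale, shift) kept — shift and scale are optimized jointly and both
reported. Labeled per-column counts are `s × Σ labeled`. The packaged
reference NeuN profile is synthetic (a smooth layered density with an L4
peak, scaled to 3500 neurons in L5 per average column); real-data users
supply their own measured reference.

## Synthetic cohort generator

The generator's defaults encode the published group statistics and are the
conditions under which the test suite and acceptance script run.

**Group calibration.** Soma depths: Gaussian with mean ± SD of
1042±105 (POm), 1055±97 (SC), 1131±110 (Pons), 1154±98 (Sp5C) µm. Rates
(ongoing 7.2/1.3/1.8/4.3 Hz; onset elevation 5.1/1.7/4.5/6.9 Hz; onset
probability 0.66/0.23/0.38/0.64; sustained elevation 0.8/2.3/3.3/3.3 Hz)
are group means whose published uncertainties are standard errors over
N=5 cells; per-cell SDs are therefore SE·√5. Burst fractions (100 Hz:
5.2/13.5/5.2/4.6 % of APs; 200 Hz: 2.1/6.2/0.4/1.5 %) vary per cell with a
50% relative SD. Default group sizes 10/6/16/11 (sum 43, the recorded
sample size) are proportional to the labeled-PT abundances per average
barrel column (256/174/421/284; 7/5/12/9 % of L5 NeuN); this mix reproduces
the published pooled means (3.5 Hz ongoing, 7.5 Hz onset-window rate)
directly from the per-group calibration. 25% of cells carry a second
target label (never pairing POm with Sp5C); dual cells inherit all
generative parameters from their primary group, the second label being
annotation only. Trials per cell default to 25 (range 20–30).

**Mean-preserving truncation.** Per-cell parameters are drawn from
Gaussians truncated below (rates at 0, depths at 0). Because several
calibrated SDs exceed their means (e.g. POm sustained 0.8 Hz with per-cell
SD 3.1 Hz), plain resample-until-positive sampling would inflate group
means materially (≈2.8 Hz instead of 0.8 Hz for POm sustained). The
generator instead shifts the pre-truncation location (solving
`E[X | X > lo] = mean` with a bracketed root-finder on the inverse Mills
ratio) so post-truncation means equal the calibrated values exactly. The
post-truncation SD is smaller than nominal in those extreme cases; the
mean, which every recovery check targets, is preserved.

**Spike trains.** An inhomogeneous Poisson base process (thinning from the
peak rate) with: ongoing rate before 0; ongoing + onset elevation on
[0, 100); ongoing + the group's sustained envelope on [100, 700); linear
return to baseline on [700, 800). Envelope shapes preserve the mean
elevation over [100, 700): flat/constant are constant at the sustained
rate; "decaying" falls linearly from 2× to 0; "late ramp" is 0 before
500 ms and 3× after. Burst doublets: a fraction `f = b100/(2 − b100)` of
ongoing-period base spikes is followed by a second spike (ISI ≤5 ms with
conditional probability `b200/b100`, else 5–10 ms); the pre-onset base rate
is divided by `1 + f` so the total ongoing rate matches the target. Onset
reliability: when the Poisson probability of ≥1 onset-window spike exceeds
the target onset probability, all of a trial's onset spikes are deleted
with the complementary probability; when it does not, the onset rate
dominates and no thinning occurs — so measured onset probabilities sit at
or somewhat below the calibrated values for low-rate cells.

*Known limitation:* measured burst percentages exceed the calibrated
fractions because the Poisson base process already produces chance ISIs
≤10 ms at these rates (e.g. ~13% at 7 Hz), whereas real PT spiking is more
regular than Poisson between bursts. The injected fractions control the
*excess* short-ISI mass; no recovery check targets absolute burst
percentages.

**Morphologies.** Trees are constructed to match per-layer length targets
(POm 12.7, SC 13.2, Pons 16.8, Sp5C 13.8 mm totals) and branch-point
targets (66/77/98/90) exactly: basal stems spread horizontally in the
soma's layer; an apical trunk ascends (and a basal subtree descends) across
layer bands, accumulating each layer's length through horizontal
excursions at mid-layer depth and carrying branch points as bifurcation
twigs. The per-layer split of the totals is a package calibration chosen to
encode the published laminar contrasts (POm sparsest in L5A; SC richest in
L5A and sparsest in L5B; Pons most complex in L1; Sp5C least complex in
L4). Per-cell variability multiplies the targets by group-specific scale
factors matching the published total-length and branch-point SDs, plus 8%
per-layer jitter. Because all excursions are horizontal and crossings
vertical, extracted per-layer quantities equal their targets (lengths to
construction tolerance, branch points exactly) — the geometry (square-loop
excursions, perpendicular twigs) is schematic, not a model of realistic
dendrite shape, and features like tuft extent or branch order are
internally consistent rather than biologically calibrated.

**Soma fields.** Each slice captures a Uniform(0.6, 1.0) column-equivalent
of somata: NeuN depths sampled from the reference layered density, labeled
depths from the group depth Gaussians with per-column totals from the
calibration, all shifted by an integer number of 50 µm bins (pia
mis-registration up to ±100 µm) that the alignment stage must undo. Counts
are Poisson. Ground-truth per-column totals are recorded for recovery
tests (the full pipeline recovers them to a few percent with 12 slices).

## What passing tests show — and what they do not

Recovery tests demonstrate that the pipeline's estimators are consistent
with the generative model at the published sample sizes and tolerances:
group means within 3 SE, laminar targets within 5%, per-column counts
within 10%, and classification confidences at the published levels
(leave-one-out over 100 seeded cohorts at n = 5/5/5/4: median mean
confidence ≈ 90% in the combined 3-feature space and ≈ 95% with SI1/SI2
appended). They do not show that real PT recordings meet these numbers:
the synthetic cohorts assume Gaussian parameter variation, Poisson spiking
with stylized envelopes, schematic dendritic geometry and exact layer
registration, none of which hold exactly in vivo.

## Problem sizes and determinism

Simulations are sized to run on one CPU in seconds to a few minutes: 100
cohorts of 19 cells for the classification surrogates, 200 cells for
single-group rate recovery, 50 replicate 43-cell cohorts for pooled evoked
rates, 12 slices for density recovery. Every stochastic stage consumes a
`numpy.random.Generator` seeded from a single integer; fixed seeds make
cohorts and the entire report bundle byte-identical across reruns.
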