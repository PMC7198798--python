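# Methods

`immunet` reconstructs directed, signed immune-signaling networks from
short plasma-cytokine time courses collected around a maximal exercise
challenge, and compares the circuits recovered in two subject groups
(healthy controls, HC, and an illness group, GWI). This note documents the
models, the parameter choices that matter, what the synthetic cohort does
and does not emulate, and the numerical decisions made where the design
was genuinely open.

## Preprocessing

Raw panels hold pg/ml concentrations of 16 cytokines at 8 labelled draws
(rest, early exercise, peak effort T1, then +10/20/30/60 min and 4 h).
The chain is:

1. **Non-detect replacement.** Zero readings are below the assay floor;
   each is replaced by the minimum strictly positive level of that
   cytokine across all subjects in both groups. Idempotent; a cytokine
   that is zero everywhere is an error (no floor exists).
2. **Uniform-grid interpolation.** Piecewise-linear interpolation at a
   3-min step (the smallest spacing in the draw schedule) from the first
   to the last observation — no extrapolation.
3. **Fold-change normalisation.** Each value is divided by the geometric
   mean of the healthy-control resting (T0) values of that cytokine,
   i.e. `2^(log2 v − mean_HC log2 v_T0)`. Baselines use the raw T0
   observations, not interpolated values.
4. **Recovery slice.** Analysis is restricted to 0–240 min after peak
   effort (81 grid points at 3 min), the window in which the groups'
   recovery dynamics differ.

The time axis is anchored at peak effort (T1 = 0 min) so subjects with
different times-to-peak align on recovery; label times are advisory,
minutes are authoritative. Outlier subjects are removed only through an
explicit exclusion list — the study this emulates removed one control
subject by inspection, and no numeric rule reproduces that judgement.

## Trajectory divergence

Per-cytokine separation of two subjects' recovery curves is measured by
an **amplitude–shape semi-metric**: both curves are linearly re-sampled on
the union of their grids, and

    d(x, y) = m / (m + (range(x) + range(y)) / 2),   m = mean |x(t) − y(t)|.

This satisfies d(x,x) = 0, symmetry, and d ∈ [0,1] (the triangle
inequality is not claimed), and handles unequal lengths. The published
SMETS measure the study used is defined in a separate reference and its
parameters are not recoverable from the text, so the distance is a
pluggable strategy (`series_distance(..., method=...)`); a path-normalised
dynamic-time-warping variant is included.

Group comparison follows the study's resampling: per repeat, 11 random
subsets of 10 subjects from each group (leave-one-out in the 11-subject
group, leave-two-out in the 12-subject group); all within- and
cross-subset pairwise distances are pooled over 11 repeats, and inter vs
pooled-intra distributions are tested with Welch's t and the Wilcoxon
rank-sum test. Pairwise distances between fixed subjects are computed
once and re-used across subsets.

**Caveat — pseudo-replication.** The resampled lists re-use each subject
pair many times, so these p-values are anticonservative as hypothesis
tests: under a null cohort (both groups generated from one model) the
empirical rate of rank-sum p < 0.05 is ≈ 0.74 per cytokine, not 0.05.
The distributions are faithful to the published procedure and useful as
descriptive summaries; they are not calibrated tests, and the acceptance
suite records this honestly (one deliberately failing check).

## Functional-set aggregation

The 16 cytokines map to 9 functional sets (monokines MK\*, lymphokines
CK\*): MK1A/MK1B (IL-1a, IL-1b, IL-8, IL-12 — two co-expression patterns
of one block), MK2 = IL-10, MK6 = IL-6, MK15 = IL-15, MK23 = IL-23,
CK1 = {IL-2, IFNg, TNFa, TNFb}, CK2 = {IL-4, IL-5, IL-13}, CK17 = IL-17.
Multi-cytokine sets are scored by principal components of the
mean-centred **log2 fold-change** block pooled over all subjects, both
groups, and all recovery time points — one shared coordinate system, so
scores are comparable across groups. Centring only (no variance scaling):
fold change already places cytokines on a common scale. Components are
sign-fixed so the largest-magnitude loading is positive. The MK1 block is
always scored as two patterns (PC1 → MK1A, PC2 → MK1B), the convention
under which the fixed nine-node universe is defined; for other blocks a
second component is diagnosed (logged) when PC1 explains < 80 % of block
variance but the nine-node universe scores them by PC1. Singleton sets
bypass PCA: score = centred log2 fold-change.

## Rate-model inference

Scores follow the linear rate model dx/dt = A·x with `A[i, j]` the signed
influence of set *j* on the rate of set *i* (positive = activation,
negative = inhibition, zero = none). Per subject:

1. **Rates** by central differences on the 3-min grid (one-sided at the
   two endpoints). The regression then uses interior samples only: the
   endpoint estimates are first-order accurate and sit at the
   highest-leverage extremes of the trajectory, and including them
   measurably corrupts the fit (recovery F-score capped near 0.5 in
   noise-free simulation versus 0.8–1.0 without them).
2. **PLS regression** of all rate rows on all score rows jointly
   (predictors standardized by default), delegated to scikit-learn.
3. **Broken-stick retention.** The number of latent components kept is
   the longest prefix whose predictor-variance fractions satisfy
   `f_k > λ·b_k`, with `b_k = (1/p)·Σ_{i=k..p} 1/i` the expected k-th
   largest fragment of a randomly broken unit stick; `λ` scales the
   stick (λ → 0 retains all components; larger λ is stricter).
4. **Pruning.** Off-diagonal coefficients below `θ · max|off-diagonal|`
   are zeroed; surviving signs are the edge signs. Self-degradation
   (diagonal) terms are fitted but excluded from edge scoring.
5. **Calibration.** (λ, θ) maximise the mean edge F-score of the
   training subjects' networks against a reference network, by
   constrained simulated annealing (geometric cooling 0.95, 200
   iterations) seeded from a deterministic coarse grid scan. Box
   constraints: λ ∈ [1e-12, 4] with log-scale proposals, θ ∈ [0, 0.5].
   The λ lower bound is deliberately tiny: the predictor-variance
   spectrum of a smooth recovery trajectory decays below 1e-6, so any
   lower bound of ordinary magnitude caps retention at ~3 components and
   makes a nine-node influence matrix unidentifiable even from perfect
   data; the small-λ limit recovers the keep-all-components case when
   the data genuinely support it, and under noise the annealer selects
   larger λ on its own.

Edge agreement with a reference uses directed (source, target) matching
(optionally sign-sensitive): recall = matched/|reference|,
PPV = matched/|inferred|, F = harmonic mean.

**What recovery means here.** On densely sampled noise-free score
trajectories (81 points over 240 min) the calibrated chain recovers
ground-truth networks at mean per-subject F ≈ 0.95. On the realistic
8-draw panel, trajectories are piecewise-linear interpolations of six
recovery samples; per-subject structure recovery from such data is poor
(F ≈ 0.3) for any method of this family — the pipeline's robust outputs
at study scale are the consensus/characteristic circuits and ensemble
contrasts, not individual subject networks.

## Consensus and the characteristic circuit

100 random subsets of 10 subjects are drawn per group (subsets may repeat;
with 11 subjects there are only 11 possible). Within a subset, an edge
enters the consensus network when ≥ 6 of the 10 subject networks carry it
(direction-only support); its sign is the majority sign among supporters
(ties: dropped, logged) and its weight the median supporting weight of
the majority sign. The **characteristic** network keeps edges present in
all 100 consensus networks (unanimity). Subject networks do not depend on
the subsample, so they are inferred once and cached; the procedure is
then exact edge-frequency analysis. Edge counts are monotone
non-increasing with consensus strictness by construction.

## Topology comparison

* **Graph edit distance**: Σ|a_ij − b_ij| over off-diagonal entries — the
  cost of edge edits weighted by weight differences. The normalised
  default first scales each matrix by its own largest off-diagonal
  magnitude and divides by N(N−1), making values comparable across
  ensembles (range [0, 2]); raw mode is the literal sum. Significance of
  inter- vs intra-group GED uses the same two-sample tests as the
  divergence module, on pairwise GEDs within and between ensembles.
  The positive control (distinct generating networks) is run with
  observation noise off so the group signal is present in the compared
  networks; the null calibration runs under full noise. Ensemble members
  that share subjects (consensus networks) are correlated, which inflates
  inter vs intra contrasts — null calibration is therefore checked at the
  subject-network level.
* **Centralities**: weighted in/out degree (sums of |w|), betweenness
  normalised by (N−1)(N−2), and unnormalised harmonic in/out closeness,
  with edge length 1/|w| and signs ignored (networkx backs the
  shortest-path metrics; tests verify them against an independent
  Dijkstra oracle). HITS hub/authority scores use L1-normalised power
  iteration on |w| (authority ∝ B·h, hub ∝ Bᵀ·a with B = |A|), which
  converges to the dominant eigenvectors of BBᵀ/BᵀB.
* **Motifs**: feedforward loops are ordered triples X→Y→Z with direct
  X→Z, coherent iff sign(X→Y)·sign(Y→Z) = sign(X→Z), typed C1–C4/I1–I4 by
  the standard sign-triple table (C1 (+,+,+); C2 (−,+,−); C3 (+,−,−);
  C4 (−,−,+); I1 (+,−,+); I2 (−,+,+); I3 (+,+,−); I4 (−,−,−)) — kept in
  one table so the convention can be corrected without touching logic.
  Feedback loops are simple cycles (default length ≤ 3) labelled by the
  product of member edge signs.

## Receptor blockade in silico

An antagonist of a mediator's signal removes all outgoing edges of that
node (column of A); the node remains regulatable. The search
exhaustively evaluates all 9 single and 36 paired blockades plus the
no-blockade baseline, scoring each by the (mean) GED between the edited
source circuit(s) and the target circuit(s) — over all cross pairs when
ensembles are given — and ranks ascending with lexicographic
tie-breaking.

## Qualitative dynamics

A fuzzy-logic discrete-state engine (in the spirit of published
discrete-state network simulators, whose exact semantics are not public):
states live in [0,1]; a node's target is basal when it has no activators,
else `a·(1−h)` with `a`/`h` the fuzzy-OR (max) of activator/inhibitor
contributions (normalised |weight| × regulator state). A logistic
reshaping centred at 0.5 with steepness `s` sharpens the target and each
node relaxes as `x ← x + (Δt/τ)·(σ_s(target) − x)`, clamped to [0,1].
Per-run time constants are truncated-positive Gaussians (μ = 10, σ = 2
steps); defaults `s = 8`, Δt = 1, horizon 100, 100 runs. The three
scenario circuits (source, target, treated) share the same sampled
parameters per run for paired comparison. Initial states are set to an
elevated "peak-effort" vector and relax freely. Per-node **rescue** is
`1 − RMS(treated − target)/RMS(source − target)` on ensemble means
(1 = perfect rescue, 0 = no change, < 0 = worse; near-zero denominators
report 0 with a warning).

## Synthetic cohort

The generator emulates the study design, not its biology: two groups
(11 + 12 subjects), ground-truth 9-node networks drawn at density 0.3
with signs 60 % positive, magnitudes uniform (0.2, 1]×0.04 per minute
(relaxation over tens of minutes, resolvable on a 3-min grid), and a
diagonally dominant negative diagonal (stability margin 0.01/min).
Subjects deviate by sign-preserving log-normal weight jitter (σ = 0.2)
and 10 % edge dropout. Node dynamics relax from an elevated peak-effort
state (mean 1.5× basal) toward basal = 1 (fold-change neutral), by the
exact matrix-exponential solution (Euler–Maruyama with sub-stepping when
process noise is requested). Cytokines read out their set's node state
multiplicatively, `ref·2^(loading·(x−basal))·exp(N(0, cv))`, sampled at
the 8 nominal draw times with per-subject timing jitter and censored
below the detection floor — so positivity, log-normal noise and
non-detects mirror real panels. The MK1 block carries two latent
patterns (IL-1a/IL-1b on MK1A, IL-8/IL-12 on MK1B) so the two-component
scoring has a ground-truth counterpart. `emit_score_cohort` bypasses the
cytokine read-out and returns densely sampled score trajectories (the
noiseless limit of the chain, which is affine in the node states) for
structure-recovery experiments; its measurement noise is additive on the
log-scale scores, the score-level equivalent of multiplicative
concentration noise.

What the generator does **not** emulate: real immunokinetic rate
constants or absolute pg/ml ranges, nonlinear or time-varying signaling,
assay plate effects, and subject-level covariates. Passing recovery tests
therefore shows the machinery is correct and well-conditioned, not that
real 8-draw cohorts support per-subject network recovery (they do not;
see above).

## Reproducibility and numerics

All randomness flows from explicit seeds; pipeline stages derive seeds
from one master seed via a stable counter scheme (`stage_seed`), so any
stage can be re-run in isolation. Reports round floats to 6 significant
digits so repeat runs are byte-identical. Degenerate inputs are handled
explicitly: all-zero coefficient matrices prune to an empty network with
a warning; empty inferred networks report PPV 0; zero-variance distance
distributions report p = 1; sign ties in consensus drop the edge and log
it. Problem sizes in the test and acceptance suites (e.g. 3–20 seeds per
statistical check, 25–50 null replicates, 100-subsample ensembles) were
chosen to give stable verdicts at desk scale.

## Known limitations

* The packaged 50-edge reference network is a synthetic stand-in with
  plausible signs; analyses against it exercise the machinery, not the
  literature.
* The divergence p-values are descriptive (pseudo-replication, above).
* Per-subject networks from 8-draw panels are noise-dominated; interpret
  only consensus-level structures at that sampling density.
* The fuzzy-logic engine is a documented reimplementation in spirit, not
  a port; its parameter defaults are stand-ins chosen for smooth
  relaxation over a 100-step horizon.
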