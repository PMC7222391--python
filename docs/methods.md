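# Methods

## The analysis in one paragraph

`mstnet` turns multi-channel EEG trials into frequency-band-specific
functional networks and compares their topology across the four quadrants of
the valence–arousal plane. For each trial and band the signal is band-pass
filtered, the instantaneous phase is taken from the analytic signal, and the
phase lag index (PLI) is computed for every channel pair, giving a 32 × 32
connectivity matrix. Per subject and condition the trial matrices are
averaged and reduced to their maximum-weight spanning tree, whose shape is
summarized by a small set of scale-free metrics (leaf fraction, normalized
maximum degree and betweenness, diameter, eccentricity, tree hierarchy) plus
the whole-network mean PLI (MPLI). The subject × condition metric table then
feeds a 2 (arousal) × 2 (valence) within-subject ANOVA and FDR-corrected
paired contrasts.

## Phase lag index

For two phase series φ_i(t), φ_j(t),

    PLI(i, j) = | ⟨ sign(φ_i(t) − φ_j(t)) ⟩_t |,

with the difference wrapped to (−π, π]. PLI is 0 when the phase-difference
distribution is symmetric around 0 or π — in particular for zero-lag
components such as a common source seen by several electrodes (volume
conduction) — and 1 when one channel consistently leads. We implement the
sign through sign(sin Δφ), which is algebraically identical on the wrapped
interval and maps differences of exactly 0 or π to 0; differences within
1e−9 of those points are treated as exact to keep the hand-countable cases
exact in floating point.

Numerical choices:

* **Filter.** Zero-phase FIR band-pass, Hamming window, transition width 25%
  of the band width. The symmetric filter is applied in a single FFT-based
  pass with centred alignment (exactly zero-phase for a linear-phase FIR);
  edges are reflect-padded. Band edges at or above Nyquist raise before any
  work.
* **Phase.** Analytic signal via the Hilbert transform (FFT length padded to
  the next fast size). `edge_trim` (default 0.5 s per side) removes filter
  and transform edge artefacts before the PLI; the PLI wrapper additionally
  requires ≥ 512 usable samples. A numerically silent channel has no defined
  phase and raises.
* **Bands.** θ 4–7, α 7–13, β1 13–20, β2 20–30, γ 31–45 Hz. The default
  sampling rate is 128 Hz and trials are 60 s; DEAP-shaped input (40 × 8064
  arrays at 128 Hz) is reduced to the first 32 rows (EEG) with the first 3-s
  baseline dropped.
* **Aggregation level.** One PLI matrix per trial, then an element-wise mean
  per subject × condition before tree construction (default). The
  alternative — per-trial trees whose metric values are averaged — is
  available as `aggregation="trial-metric-average"`.

## Spanning trees and metrics

The backbone is the maximum-total-PLI spanning tree, built by Kruskal's
algorithm: rank all 496 pairs from highest to lowest PLI and add each edge
that joins two components until the 32 nodes are connected by 31 edges.
Equal weights are broken by lexicographic (i, j) node-index order, making
the tree deterministic even for degenerate matrices. Optimality is verified
in the tests against exhaustive enumeration of all labelled spanning trees
for N ≤ 6 and against networkx's independent implementation at N = 32.

With N nodes, M = N − 1 edges, L leaves and raw degrees k_i:

| metric | definition |
| --- | --- |
| degree_max | max_i k_i / M |
| leaf fraction Lf | L / M |
| BC_max | max normalized betweenness, 1/((N−1)(N−2)) · Σ ordered pairs separated |
| diameter D | max_{i,j} d(i, j) / M |
| eccentricity | mean_i max_j d(i, j) / M |
| tree hierarchy Th | L / (2 · M · BC_max) |

Betweenness is counted topologically (tree paths are unique regardless of
weights). Th is undefined (reported missing) only for N ≤ 2, where BC_max is
zero; a perfect star gives Th = 0.5 exactly.

**Distance convention.** `d(i, j)` can be counted in hops (every edge length
1) or as weighted path length with per-edge length 1 − PLI (strong couplings
are short). The weighted convention is the default: hop distances on a
32-node tree are bounded below by 2/31 ≈ 0.065 after normalization, which is
coarser than the diameter differences the metric is meant to resolve, while
1 − PLI lengths vary continuously with connectivity strength. Both
conventions are implemented, tested against closed forms (star, path,
uniform-weight path) and recorded in the output as `distance_convention`.

**Average trees.** Within a condition × band, subject trees are overlaid on
the common node set; each edge's weight is the number of subjects whose tree
contains it. The condition's average spanning tree is the maximum-count
spanning tree of this overlap graph (same Kruskal + tie-break), and nodes
with raw degree ≥ 3 are reported as hubs (degree ≥ 4 flagged `major`,
degree 3 `minor`).

## Group statistics

Trials are assigned to HAHV/HALV/LAHV/LALV by thresholding the 1–9 ratings:
[1, 4] is low, [6, 9] is high, and the open middle band (4, 6) is
unclassified on either axis. The intervals are closed at 4 and 6 because the
ratings may be continuous and boundary trials are better classified than
silently dropped. Subjects lacking at least one trial in any condition are
excluded and logged.

The 2 × 2 within-subject ANOVA is computed exactly through per-subject
contrast scores: for each effect (arousal, valence, interaction) the four
condition values collapse to one score per subject with ±½ weights, and
F = t² of the one-sample t-test on the scores, df = (1, n − 1). For
two-level factors this is algebraically identical to the classical
sums-of-squares decomposition with the effect-by-subject interaction as the
error stratum (the tests verify this against an explicit SS oracle and
against pingouin), and sphericity is trivially satisfied. The effect size is
partial η² = SS_effect / (SS_effect + SS_error). If the contrast scores have
zero variance, F is 0 (all-equal data) or reported as infinite with p = 0
and η² = 1 (a noiseless planted effect).

Paired two-sided t-tests are run on the four fixed contrasts HAHV−LAHV,
HALV−LALV, HAHV−HALV, LAHV−LALV. Zero-variance nonzero differences leave t
undefined (NaN); identical vectors give t = 0, p = 1. FDR correction is
Benjamini–Hochberg (via statsmodels); the default adjustment family is the
four contrasts of one metric within one band, with an option to pool all
metrics of a band.

Degrees of freedom are always reported explicitly as (df_effect, df_error)
and the subject count is taken from the data, so the pipeline is agnostic to
how many subjects survive exclusion.

## The synthetic generator

No generative model exists for the real recordings, so the simulator is an
artifact-side construction with a known, analyzable phase-coupling structure
— it validates the pipeline, not the physiology.

Signal model per trial: every channel owns a latent analytic narrowband
Gaussian oscillation, synthesized spectrally (i.i.d. complex Gaussian
coefficients on the in-band positive frequencies, inverse FFT), which is
exactly band-limited and analytic by construction. A planted coupling
(i → j, strength s, lag θ) mixes channel i's oscillation, rotated by
e^{−i(θ + η(t))}, into channel j at weight s, while j keeps its own
oscillation at weight 1 − s; η(t) is slowly varying Gaussian phase jitter
with SD (1 − s)·π/2 (0.5-s smoothing), so s = 1 gives a deterministic lag
(PLI → 1) and intermediate s gives PLI strictly between 0 and 1 with a
monotone link to s. For a pairwise planted graph this reduces to the
"phase-shifted copy mixed with independent narrowband noise" construction;
expressing it through per-channel latents keeps hub couplings strong when
one channel leads many others. Lags of exactly 0 or π are rejected at
configuration time because the PLI is blind to them by design.

On top of the coupled structure each trial receives: a zero-lag narrowband
common source added to all channels (`common_source_gain`, default 0.5) as a
volume-conduction-like confound that the PLI must reject; background
narrowband noise (amplitude 0.5) in the non-coupling canonical bands so all
five bands carry activity; and white measurement noise (`noise_sd`, default
0.5).

Group studies follow the 2 × 2 design: condition coupling = baseline
(default 0.4) + `arousal_effect` for high arousal + `valence_effect` for low
valence + `interaction_effect` for both, plus a Gaussian per-subject
intercept (SD 0.05, clipped into [0, 1]); deterministic effect combinations
outside [0, 1] are configuration errors. The sign conventions make high
arousal and negative valence strengthen coupling, matching the direction of
the emotional-EEG findings the pipeline is designed to detect; both are
plain signed numbers and can be flipped. The default planted topology is a
hub-and-spokes graph anchored at T7, so stronger coupling pulls the
recovered tree toward a star (higher leaf fraction and maximum degree, lower
diameter and eccentricity) — the same signature direction the statistics
stage looks for. Defaults are 32 subjects, 10 trials per condition, 60-s
trials at 128 Hz, matching the dimensions of the DEAP-style studies the
pipeline targets. Everything is deterministic per seed (per-subject seed
streams spawned from the study seed).

What the generator does **not** emulate: dipole/forward-model geometry, 1/f
spectra, non-stationarity, eye/muscle artefacts, or realistic inter-channel
covariance. Passing the validation suite therefore shows that the pipeline
recovers planted phase-lag structure and calibrated statistics under this
model — not that real recordings satisfy the model.

## Validation problem sizes

The stochastic validation runs are scaled so the whole suite stays cheap
while keeping the statistical claims meaningful: Type-I calibration uses 200
replicate null studies of 20 subjects with one 8-s trial per condition
(rejection rate checked against 0.05 ± 0.03, i.e. ±2 binomial SE at 200
replicates); direction recovery uses 50 replicates of 12 subjects with a
planted arousal effect of +0.25 on a 0.35 baseline. Under the null the
Type-I rate of the exact 2 × 2 ANOVA does not depend on trial length, and
the planted-effect replicates are strongly powered at these sizes, so the
short trials trade nothing but Monte-Carlo smoothness.

## Known limitations

* The published condition means/SDs bundled as an optional benchmark come
  from real recordings; synthetic studies are not expected to match them,
  and the comparison is only meaningful when the pipeline is run on the
  actual DEAP release (which must be obtained separately and converted to
  the documented array layout).
* The per-edge length 1 − PLI used for weighted distances is one defensible
  reconstruction of "optimal path" on a similarity-weighted tree; outputs
  carry the convention tag so hop-based results can be produced alongside.
* Resampling is out of scope: input must already be at 128 Hz.
* The exact 2 × 2 contrast ANOVA does not generalize to factors with more
  than two levels; that is outside this design.
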