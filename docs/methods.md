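# Methods

This note documents the models, conventions, default parameters and known
limitations of the `ripplelamina` pipeline. It is the companion to the API
docstrings: what follows explains *why* the defaults are what they are and
what the synthetic validation does and does not establish.

## Conventions

LFP is in microvolts, time in seconds, channels indexed 0-based from dorsal
to ventral. All filters are Butterworth run forward-backward
(`sosfiltfilt`), i.e. zero-phase: event timing quantities (ripple peaks,
sink lags, theta control points) are never biased by filter group delay.
All stochastic routines accept an explicit seed; the pipeline derives
per-stage seeds from one global seed with `numpy.random.SeedSequence`, so a
re-run with the same configuration is bit-identical.

## Ripple detection and validation

Detection operates on the difference between the CA1 pyramidal-layer trace
and a ripple-free reference channel. The differential signal is band-passed
at 80–250 Hz (ripple band) and 200–500 Hz (control band); envelopes and
phases come from the Hilbert transform. Envelope peaks above five times the
session median of the ripple-band envelope are candidates; peaks within
20 ms merge keeping the larger; onset/offset are the half-threshold
crossings. Candidates are validated by four criteria: ripple-band power at
least twice the reference channel's, mean frequency above 80 Hz, at least
four cycles (unwrapped phase difference over 2π), and ripple-band power at
least twice the control band's. The 5×median threshold is applied to the
ripple-band envelope (the natural reading of peak search "within the ripple
band"), and the median is taken over the whole session; a windowed median
made no difference on stationary synthetic noise and adds a parameter.

The reference channel for the pyramidal layer is the one maximising the
Welch ripple-band score, power(80–250 Hz)/power(70–300 Hz), with 4-s Hann
windows at 50% overlap; ties resolve to the lowest index. An "isolated"
ripple has no neighbour within ±250 ms; PETHs and triggered averages use
isolated events only.

## Theta cycles and sleep-state segmentation

The theta component is by default a zero-phase 5–12 Hz band-pass of the
reference-channel LFP. This is a deliberate substitution for a masked-EMD
sift: the cycle-validation rules (half-periods within 31–100 ms,
peak-to-peak within 71–200 ms, extrema above the low-frequency envelope)
do the heavy lifting, and any caller can supply a different narrowband
component. Note the two rules interact: a pure 16 Hz oscillation passes the
half-period rule but fails the 71-ms peak-to-peak minimum, so the retained
band is effectively ≤14 Hz. Each valid cycle gets six control points
(zero-crossing, peak, zero-crossing, trough, zero-crossing, next peak)
mapped to phases (−π/2, 0, π/2, π, 3π/2, 2π); instantaneous phase is the
piecewise-linear interpolation, so the peak is 0 and the trough π by
construction.

NREM segmentation uses the theta-power ratio (5–10 Hz over 0.1–10 Hz) from
a 2-s/90%-overlap spectrogram, downsampled to 1 Hz and split by a
2-component Gaussian mixture; NREM additionally requires speed below
mean + 1.5 SD. REM is a low-speed high-ratio epoch immediately following at
least 2 minutes of NREM. When the ratio distribution is effectively
unimodal (component separation below 1 pooled SD, or a component weight
under 5%, or the 1-component fit winning by BIC) the mixture split is
meaningless; the segmenter then falls back to an absolute 0.5 ratio
threshold and flags the session low-confidence.

## CSD signatures and laminar classes

CSD is the negated second spatial difference, −(LFP[n−1] − 2·LFP[n] +
LFP[n+1]), on interior channels; negative values are sinks. No conductivity
scaling is applied — every downstream use is unit-variance normalised or
percentile-ranked. The full-session CSD is smoothed along the laminar axis
with a Gaussian of σ = 50 µm (expressed in channel units via the probe
spacing, reflective boundary), which equalises the spatial resolution of
probes with different spacing; per-ripple signatures are computed on the
smoothed CSD (the same motivation — per-event signatures should not depend
on probe pitch). The signature is the per-channel time mean over the
half-open 50-ms window [peak−25 ms, peak+25 ms).

Three labelling routes are provided. (1) Dominant sink: the CA1 stratum
(oriens, pyramidale, radiatum, lacunosum-moleculare) holding the most
negative signature value, "no sink" if none is negative. (2) PC1 of the
signature matrix, sign-fixed so its mean stratum-radiatum weight is
negative; strengths above the 70th percentile are Rad, below the 30th LM,
the rest intermediate, with boundary ties going to intermediate. (3) The
normalised lacunosum-moleculare CSD (mean over the central LM channel ±1
neighbour, divided by its SD across events); lowest 30% LM, top 30% Rad.
Route 3 is the ground truth for the waveform classifier.

## Waveform classifier

Each ripple's 200-ms peri-peak pyramidal trace is low-passed at 30 Hz
(isolating the sharp-wave component), z-scored per trace, and embedded
with a 6-component PCA. The preprocessing statistics (PCA basis) are fit on
training folds only; the z-score is per trace so it cannot leak. The LDA
classifier is validated leave-one-subject-out with the training classes
downsampled to the smallest class (default 1,000 repeats; tests and the
desk-scale runs use 25–100), each repeat paired with a label-shuffled null
model trained identically. The chance-normalised gain is reported as
100·(acc_true − acc_null)/acc_null per fold; this is a declared convention —
percentage gain reports in the literature rarely state their
normalisation, and this choice is dimensionless and reproduces the right
magnitudes for moderately separable classes.

## Up/Down states and ripple sequences

The dentate molecular-layer CSD energy (mean rectified CSD over the layer's
channels, 1-s median filter, 5 Hz, z-scored) is segmented with a
2-component Gaussian mixture whose parameters initialise a 2-state Gaussian
HMM (uniform start, 10 restarts, best likelihood kept); the Viterbi path is
decoded and the higher-mean state is Up. A session is usable for
state-conditioned proportions when at least 100 Up and 100 Down epochs are
detected. Unimodality (mixture separation < 0.5 SD or a 1-component BIC
win) flags low confidence. Ripple chains are maximal runs with inter-event
gaps under 250 ms; transition matrices over {Rad, intermediate, LM} are
normalised by subtracting the mean of 1,000 label shuffles that preserve
per-class totals. LM-proportion denominators use LM/(LM+Rad) by default;
`include_intermediate` switches the convention. Energy-bin edges are
equally spaced over [−2.5, 2.5] z in 10 bins.

## Population vectors, decoding and the margin shuffle

Population vectors are spike counts per unit in the half-open 50-ms
peak-centred window. The margin-preserving shuffle expands every spike to
its unit index, permutes the list, and refills events column by column, so
each unit's total and each event's population count are conserved exactly
while within-event identities randomise. Note the shuffle does *not*
produce zero pairwise correlation: conserved event totals induce a small
common-rate correlation, and the analytic multinomial level
p_i·p_j·(VarT − ET) over the geometric mean of the variances is the correct
null — the tests compare against it, not against zero.

Ripple-type decoding uses L2 logistic regression (fixed weak penalty,
C = 1 — a free choice, recorded in the configuration) on z-scored PVs of random
n-cell subsets (reported at n = 15), class-balanced by downsampling, with
20× 80/20 cross-validation; accuracy is the plug-in mutual information
(base 2) of the pooled test confusion table, without bias correction. The
plug-in bias for independent labels is (|X|−1)(|Y|−1)/(2N ln 2) bits and is
asserted in the tests. Session inclusion follows the ≥250-events-per-class
rule.

## Coactivity graphs and pattern structure

Population-conditioned coactivity regresses unit j on unit i plus the
summed activity of the other N−2 units, per ordered pair; the matrix is
symmetrised (A+Aᵀ)/2 with zero diagonal. Fully-conditioned coactivity is a
per-target ridge regression on all other units (rows are coefficient
vectors, not symmetrised). Structural balance is the proportion of closed
triads with 0 or 2 negative edges, computed with trace identities over the
positive/negative adjacencies and cross-checked against a brute-force triad
census; edges with |w| ≤ 1e−12 are absent. Gini sparsity uses the
ascending-sort rank formula (equal to the mean-absolute-difference form);
an alternative convention ranks units by a fixed cluster index; that
conflicts with ascending-order sorting and is not implemented.

ABID (angle-based intrinsic dimensionality) computes, per event, the
pairwise cosine similarities S among the normalised difference vectors to
its k = 50 nearest neighbours and reports D = k²/ΣS². The double sum
includes the diagonal (S_ii = 1), which the definition's own worked cases
pin (collinear → 1, two orthogonal at k = 2 → 2). Two biases follow and are
documented rather than corrected: with homogeneous sampling the estimator
converges to k·d/(k+d−1) (4.63 for d = 5), and on Gaussian clouds at
n = 2000 the density gradient biases it further down (≈4.12 measured for
d = 5; d = 2 and 3 land within 10% of truth). Class-balanced comparisons
subsample 100 PVs per class, 1,000 times, capping k at the subsample size
minus one. The shuffle-normalised dimensionality divides true ABID by the
ABID of within-event identity-shuffled surrogates; the participation ratio
(Σλ)²/Σλ² is the linear counterpart.

## Motifs and contribution gain

Motif extraction is the PCA/ICA assembly method: eigenvalues of the
correlation matrix of z-scored counts above the Marčenko–Pastur edge
(1+√(N_units/N_events))² determine the number of motifs; FastICA runs on
the data projected onto that subspace (10 restarts, best mean |kurtosis|
kept), weights are unit-norm with the largest-magnitude element positive.
Motif membership — needed to distinguish member cells from candidates for
aggregation — is |weight| > 2 SD of that motif's weights, a standard
assembly-literature convention.

The contribution gain of a unit to an LM motif is its correlation with the
leave-that-unit-out motif activation in Rad events minus the same in LM
events, z-scored against margin-preserving surrogates of both classes;
units above the surrogate 97.5th percentile are significant. Aggregated
counting considers non-member units only (an "aggregated" cell is by
definition one that was not part of the motif), against a binomial
expectation over tested cells. A caveat established on synthetic data: the
surrogate null is slightly shifted for background units whenever the two
classes have different event-conditioned rate structure, because surrogates
carry a population-rate-induced correlation that motif-concentrated real
data lacks; the planted-unit asymmetry (composite units aggregate in the
forward direction and disengage in reverse) is robust to this, but absolute
background counts at |z| ≈ 2–3 are not.

## Reactivation and drift

`W_recent = A_theta·A_pre⁻¹` maps pre-sleep coactivity onto waking
coactivity; `v.T @ W_recent @ v` on a z-scored ripple PV is the
recent-to-prior balance. Matrices with condition number above 1e8 are
inverted after adding 1e−6·trace/N to the diagonal, and the result is
flagged — invertibility is not otherwise guaranteed. The balance uses the
population-conditioned (symmetric) estimator. Drift series are means over
non-overlapping 10-minute windows covering (10, 70] minutes of post-sleep
(the first 10 minutes are excluded as a settling period), normalised by
subtracting the session grand mean across bins and classes.

Model selection between a flat line (k = 1) and a·e^(−t/τ)+c (k = 3) uses
BIC = k·log n + n·log(SSE/n); the exponential is fit by least squares from
a grid of initial values (τ₀ ∈ {5, 13, 30, 60} min, both amplitude signs),
with τ bounded in [0.5, 10⁴] minutes. Bootstrap over sessions (percentile
intervals) gives τ and fit-r distributions. The τ estimator is unbiased on
synthetic drift but noisy: at desk scale (8–16 sessions of ~630 LM events)
its replicate SD is 1.5–2 minutes and occasional datasets fall 1.5 σ from
the planted value, so confidence-interval coverage of a single dataset is
approximate (percentile bootstrap is known to undercover for nonlinear
parameters at small session counts).

Pre-sleep reactivation trains per-cell linear models on pre-sleep ripple
PVs (chance-normalised by cell-identity shuffles within each PV) and
applies them per 10-minute post-sleep window; wake reactivation regresses
post-window pairwise cofiring on wake cofiring with pre-sleep cofiring
partialled out. Feature attribution predicts the binned balance from
{log time, ripples/min, active-cell fraction} with 20× 80/20 CV Pearson
accuracy and per-feature shuffles (p = fraction of shuffles with gain < 0);
time is log-transformed because the balance is exponential in time.
Sublayer decay comparison regresses per-unit reactivation on log time with
bootstrap over units/sessions against circular-shift surrogates (which
preserve the series' autocorrelation exactly).

## The synthetic generator

The generator emulates the *statistical structure* the analyses rely on,
not hippocampal biophysics. Laminar events are Gaussian-profile deflections
with per-layer amplitude vectors plus Gaussian-windowed ripple sinusoids
(durations drawn 40–100 ms; the window σ is duration/3.5 so that a
high-SNR event keeps at least four cycles above the half-threshold — an
event that fails the validation criteria by construction would not be a
ripple). Rad events: −300 µV radiatum sharp wave and a 147 Hz burst; LM
events: −250 µV lacunosum-moleculare deflection 17 ms before the peak, a
−120 µV radiatum echo 12 ms after, a +100 µV pyramidal deflection and a
125 Hz burst. Background is white noise (σ = 10 µV); event count is Poisson
at 0.5 events/s (a free parameter — occurrence is only qualitatively
constrained in vivo) with a 350-ms minimum separation.

Spike sessions have three epochs (pre-sleep 30 min, exploration 10 min,
post-sleep 71 min — post-sleep must exceed an hour for the drift binning).
Spikes are a baseline Poisson process per unit (lognormal rates around
0.6 Hz for principal cells, 10 Hz interneurons) plus Bernoulli 1-ms bins
inside 50-ms event windows with class-conditional boosts (Rad ×6, LM ×5
deep / ×2.5 superficial) and an additive 30 Hz motif gain for the units of
the expressed motif. Pre-sleep LM events express the deep-biased *core*
motif, Rad events the *composite* (core ∪ superficial-biased extras),
exploration theta cycles the *recent* motif (= the extras); in post-sleep
an LM event expresses the prior motif with probability e^(−t/τ) (τ = 13 min
by default) and otherwise the recent motif. The drift acts on the
event-level motif choice only, so occurrence frequency and sparsity are
constant over time — exactly the property the feature-attribution control
needs. A `null_config` variant removes motif gains and class differences
for negative controls.

What passing the synthetic suite shows: the analysis operations recover the
structure they target, at realistic event counts and SNR, with their
controls calibrated. What it does not show: robustness to non-stationary
noise, electrode drift, spike-sorting errors, theta harmonics, or real
laminar geometry — none of which the generator attempts to model.

## Problem sizes

Validation experiments run at desk scale: 300-s recordings (~150 events)
for detection round-trips, single simulated days for motif and coactivity
analyses, 8–16 simulated days for drift recovery, and resample counts of
100–500 where the full-scale analyses would use 1,000–100,000 (every such
count is a keyword argument; the API defaults are the full-scale values).
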