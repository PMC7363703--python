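# Methods

This note documents the models, estimators and numerical choices behind
`restdcx`, and what the synthetic cohort does and does not establish.

## Pipeline overview

Per subject: multichannel scalp EEG epochs → zero-phase band-pass and
down-sampling → regularized linear source reconstruction → one
representative time series per grey-matter parcel (SVD) → time-varying MVAR
fit over all epochs (multi-trial Kalman filter) → information Partial
Directed Coherence (iPDC) magnitudes on a frequency grid → frequency/time
average into one directed 82×82 connectivity matrix → weighted-directed
global efficiency, whole-brain and per resting-state network (RSN).
Group level: Mann-Whitney comparisons with Bonferroni correction, Cohen's d,
diagnostic metrics at the control 99th percentile, and rank correlations
with clinical covariates.

## Preprocessing

Band-pass: Butterworth of order 4 designed in second-order sections,
applied forward-backward per channel and epoch. Two-pass filtering cancels
the phase response (zero group delay) and squares the magnitude response;
band edges (default 1 and 40 Hz) are the half-power frequencies of a single
pass. Down-sampling to 250 Hz uses polyphase resampling with its built-in
anti-alias filter. Epoch selection replaces expert visual artifact marking
with an absolute-amplitude rule: consecutive non-overlapping 1-s windows,
rejecting any window whose absolute amplitude exceeds 150 µV (configurable),
keeping the first 45 survivors. Filtering precedes down-sampling.

## Source reconstruction

The forward model is a spherical single-shell surrogate: one equivalent
dipole with fixed radial orientation per solution point, scalp potential
proportional to cos(angle)/distance² (exponent configurable), columns
average-referenced. It preserves the structure of a real lead field —
linear, distance-dependent, reference-constrained — without individual
anatomy.

The inverse is Tikhonov-regularized:

    T = W Gᵀ (G W Gᵀ + λ I)⁻¹,   λ = λ_rel · mean diag(G W Gᵀ)

with λ_rel = 0.01 by default. With `spatial_weighting` on, W is a local
autoregressive-average prior, W = (AᵀA)⁻¹ with A = I − ½M, where M spreads
inverse-square-distance weights over each source's k = 12 nearest
neighbours. This reproduces the "distributed, locally smooth linear
inverse" character of LAURA-type solutions at a configurable source count
(default 500, round-robin over parcel centroids so every parcel is
covered).

Each parcel is summarised by the leading SVD component of its sources'
concatenated-epoch matrix, scaled by the singular value, with one spatial
basis per subject. The component sign is chosen so its correlation with the
parcel-mean signal is non-negative, making the output deterministic across
runs and platforms.

## Time-varying MVAR (GLKF)

The coefficient stack A_1..A_p is a latent state with random-walk dynamics,
estimated by the General Linear Kalman Filter with all K epochs entering
each time step as simultaneous trials:

    Y_t = Z_t X_t + E_t,   Y_t ∈ R^{K×n},  Z_t ∈ R^{K×np},  X_t ∈ R^{np×n}

Prediction inflates the state covariance by Q = uc · tr(P)/(np) · I; the
measurement-noise scale is the running mean innovation variance; the
innovation covariance is tracked as V ← (1−uc)V + uc·EᵀE/K. Initialization:
zero coefficients, identity state covariance, identity V. The recursion is
deterministic.

Defaults: model order p = 5 (20 ms of memory at 250 Hz), update constant
uc = 10⁻³ (slow adaptation appropriate for resting-state nonstationarity).
Both are configurable; the coefficient-recovery tests show uc = 10⁻³
recovers stationary coefficients within ±0.1 with 45×250 samples, and
uc = 10⁻² tracks an abrupt coupling change within half an epoch.

## iPDC

With Ā(f,t) = I − Σ_r A_r(t) e^{−i2πfr/fs} and ā_j its j-th column, the
influence of channel j on channel i is

    |ιπ_ij(f,t)| = |Ā_ij(f,t)| · sqrt([V⁻¹]_ii) / sqrt(ā_jᴴ V⁻¹ ā_j).

When V is diagonal this is the generalized PDC and Σ_i |ιπ_ij|² = 1 for
every source j and frequency — the normalization identity asserted in the
tests to 10⁻⁹. V is regularized by ε·I with ε = 10⁻¹⁰ × mean diagonal
before inversion. The magnitude is evaluated on the 1–35 Hz grid with
0.5 Hz spacing (69 bins, both endpoints included) and averaged over
frequency and over time after discarding the first t_burn = 25 coefficient
samples (100 ms) of Kalman transient; t_burn = 0 recovers the strict
average. The subject-level matrix is streamed in time chunks so the full
4-D tensor never materializes at 82 nodes.

## Graph efficiency

Edge weights are iPDC magnitudes; lengths are ℓ = 1/w (the standard
convention for weighted efficiency; −log mapping not implemented). Shortest
directed paths by Dijkstra; global efficiency is the mean inverse distance
over ordered pairs, with unreachable pairs contributing zero (kept in the
denominator). RSN subgraphs are induced subgraphs: paths may not leave the
subnetwork. Efficiency is homogeneous of degree one in the weights and
monotone in every edge weight; both properties are property-tested.

## Statistics

Mann-Whitney U is exact (full permutation null) when the smaller group has
at most 8 observations and there are no ties, otherwise the tie-corrected
normal approximation with continuity correction. Cohen's d uses the pooled
SD; magnitude labels at |d| ≥ 0.01/0.20/0.50/0.80/1.20/2.00 are "very
small/small/medium/large/very large/huge". The whole-brain registry runs
eight comparisons (all patients, TLE, ETLE, lesional TLE, non-lesional TLE,
non-lesional TLE+ETLE vs controls; right vs left TLE; good vs poor surgical
outcome) with Bonferroni m = 8; the RSN registry runs the first seven per
network with m = 7 over networks. Diagnostic threshold: the 99th percentile
of controls by linear interpolation between order statistics; "positive"
means strictly greater, so ties count as negative. Correlations are
Spearman (ILAE is ordinal; Pearson available), exact for n ≤ 9 tie-free
pairs by rank-permutation enumeration, t-approximate otherwise; constant
covariates yield NaN with a warning.

## Synthetic cohort

Each subject owns a stable sparse MVAR(2) network: lag-1 self-coupling
U(0.25, 0.45), within-RSN directed edges with probability 0.35 and weights
±U(0.15, 0.35), weak cross-RSN edges with probability 0.04 and weights
±U(0.05, 0.15), and a damped lag-2 self term. Patient networks scale the
cross-RSN weights by `patient_gain` (default 1.5) and plant `extra_edges`
(default 10) additional cross-RSN couplings with weights ±U(0.25, 0.45);
coefficients are uniformly shrunk if the companion spectral radius exceeds
1 − stability_margin (margin 0.1). Innovations are unit-variance diagonal
Gaussian, so ground-truth iPDC equals gPDC. Epochs are simulated natively
at 1000 Hz (1000 samples each, 500-sample burn-in per epoch), projected to
128 average-referenced sensors with white noise at 10 dB SNR by default,
and enter preprocessing like real data. Clinical covariates follow the
documented cohort proportions and are drawn independently of the network
contrast, so clinical correlations are null by construction.

Problem sizes: the end-to-end study conditions use 16 controls vs 20
patients with the default contrast; the acceptance computations run them on
12-node networks with 45 × 250-sample epochs through the direct-ROI route,
which exercises the full Kalman/iPDC/graph/statistics path while keeping a
20-seed study to a few minutes. The null calibration (gain 1, no extra
edges, 200 seeds) is evaluated on ground-truth network efficiency.

What the simulation does not emulate: realistic anatomy and conductor
geometry, non-Gaussian or structured noise (eye blinks, muscle), volume
conduction mismatch between the generating and inverting head models beyond
the dipole-vs-distributed discrepancy, and any relation between clinical
covariates and network pathology. A passing end-to-end test therefore shows
the pipeline detects cross-regional coupling differences it is pointed at —
not that real patient EEG behaves like the generator.

## Known limitations

- The spherical forward model and the LAURA-like prior are surrogates; no
  claim of anatomical accuracy.
- The Kalman innovation-covariance tracking uses a single smoothing
  constant tied to uc; very fast covariance changes lag behind.
- Subcortical parcels are attributed to cortical RSNs by a fixed editable
  table; the limbic network is deliberately the smallest subnetwork, so its
  efficiency estimates are the noisiest.
- EDF ingestion requires the optional `mne` dependency and is not covered
  by the test suite.
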