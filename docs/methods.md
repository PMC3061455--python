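# Methods

This note records the models implemented in `megbeam`, the numerical
choices behind them, what the simulator does and does not emulate, and the
design decisions taken where more than one defensible option existed.

## Data model and units

A session is a stack of epoched trials (trials × channels × samples) with
a shared time axis (t = 0 at stimulus onset, uniform step 1/fs) and the
sensor geometry. Everything is SI internally: Tesla, Volts, metres,
seconds, A·m for dipole moments. Time windows are half-open [start, stop).
The HDF5 container (groups `/data`, `/sensors`, `/meta`, all floats
float64, schema-version attribute) round-trips bit-exactly; MAT-file
structs with the same fields import to the identical in-memory object.

Preprocessing primitives: per-channel RMS over a window (averaged over
trials), channel subsetting, baseline removal (per-trial mean over a
window), trial averaging, and zero-phase band-pass filtering — a 4th-order
Butterworth run forward and backward (`sosfiltfilt`, reflect padding).
Baseline removal and filtering are separate operations; the recommended
order is baseline first, then filter, but nothing enforces it.

## Forward models

**MEG, homogeneous sphere.** The analytic closed form for the external
field of a current dipole in a spherically symmetric conductor. Two
physical facts matter downstream and are enforced by tests: the field
does not depend on the sphere radius (only the centre), and dipole
moments radial to the sphere are externally silent. Consequently a vector
lead field L_r (channels × 3) on a sphere model has rank 2, never 3. The
tests validate the implementation against an independent quadrature
oracle: the boundary potential from a Legendre-series expansion fed into
the Geselowitz surface integral, plus the primary Biot–Savart term
(agreement is ~1e-14 relative, asserted at 1%). Overlapping spheres
evaluate each channel's rows with that channel's own centre (fitted from
headshape points within 8 cm of the channel, an exposed parameter, falling
back to the global fit). Gradiometers are modelled as weighted sets of
point magnetometers declared in a plain-text coil table.

**EEG, half-space.** Potential of a dipole in a semi-infinite homogeneous
conductor (insulating boundary at a configurable plane) via a single image
dipole with the normal moment component flipped; columns are
average-referenced across electrodes, matching the automatic average
referencing of EEG data. Conductivity defaults to 0.33 S/m.

**Grids.** Regular lattices, x-fastest ordering, metres; positions and a
VOI mask travel with every lead field, and excluded voxels (outside the
conductor, at a sphere centre, or above the EEG boundary) keep their slots
so maps stay addressable. NIfTI-1 export (mm affine) is provided for
inspection.

## Adaptive beamformers

Weights are stored column-per-orientation, W_r = R⁻¹L_r(L_rᵀR⁻¹L_r)⁻¹,
algebraically identical to the usual transposed form. All solves go
through Cholesky factorizations; no explicit matrix inverses on the
channel dimension.

**Rank handling.** Because spherical MEG lead fields are rank 2, the
per-voxel normalization (LᵀR⁻¹L)⁻¹ does not exist in the radial
direction. All per-voxel normalizations (LCMV, suppression constraints,
sLORETA blocks) therefore use an eigenvalue-truncated pseudo-inverse:
directions whose eigenvalue falls below 1e-10 of the largest are treated
as unobservable and excluded from the unit-gain constraint. For full-rank
lead fields this reduces to the exact inverse, and the unit-gain identity
WᵀL = I holds to 1e-8 or better.

**Covariance.** Two estimators: the covariance of the trial-averaged data
("averaged", the evoked choice, rank-deficient for short windows — a
warning is emitted when samples < channels) and the mean of per-trial
sample covariances ("trials", full rank). Channel means are removed per
trial within the window; the normalizer is the sample count.
Regularization options: none; Tikhonov (λ · mean diagonal · I); and
minimum-eigenvalue loading, which adds the smallest eigenvalue of the
*unaveraged* covariance to the averaged one — the appropriate loading when
beamforming evoked averages.

**Localization functional.** The raw minimum-variance output power wᵀRw
is biased toward weak-lead-field (deep) voxels, because the unit-gain
constraint inflates the weights there and the amplified noise dominates.
Localization maps therefore use the neural activity index: output power
divided by projected noise power (wᵀC_n w, identity noise by default).
This is the standard scan statistic for minimum-variance beamformers; the
raw power is still available for contrast-based analyses, which
self-normalize.

**Scalar orientation.** The per-voxel orientation maximizes output SNR
under unit gain: the dominant generalized eigenvector of the pencil
(LᵀR⁻¹L, LᵀR⁻²L), solved in the observable subspace of L. This is
invariant to rescaling of R, recovers simulated orientations to well
under 5° at high SNR, and — unlike the naive "smallest eigenvector of
LᵀR⁻¹L" rule — cannot select the silent radial direction of a spherical
conductor. Degenerate pencils (e.g. isotropic LᵀR⁻¹L) are resolved
deterministically and flagged. The sign convention makes the first
nonzero component positive.

**Eigenspace projection.** w_es = E_s E_sᵀ w with E_s the top-`rank`
eigenvectors of the averaged-data covariance (raw, not regularized, by
default; callers may pass a regularized covariance). With full rank the
projection is the identity (regression-guarded). Because rank-1 projected
weights annihilate their own white-noise estimate, eigenspace
localization maps normalize by the *unprojected* weights
(`neural_activity_index(..., noise_filter=...)`).

**Coherent source suppression.** Constraint matrix C = [L_target,
U_zone], where U_zone collects the leading left singular vectors of the
concatenated zone lead fields up to 99% of the singular-value energy
(exposed parameter); the weights solve min wᵀRw subject to Cᵀw = [I; 0].
Rank-deficient constraint sets drop the weakest zone direction with a
warning. An empty zone degenerates exactly to LCMV. The scan over
non-zone voxels reports NAI-normalized power.

**Source stability index.** Scalar LCMV weights from the trials-mode
covariance are applied to the averages of two random half-splits of the
trials; the per-voxel correlation of the two half-average time series,
averaged over 20 splits (default, seeded), is the index. Odd trial counts
give the first half the extra trial. Phase-locked sources reproduce
across halves (index near 1); noise does not (|index| well below 0.2 in
the null simulations).

**Time-frequency beamformer.** Per band: zero-phase band-pass of the
whole epoch, then per active window a trials-mode covariance → Tikhonov
regularization (default λ = 0.05, the same rule applied to the control
covariance) → scalar LCMV weights from the *active* covariance; active
power wᵀR_a w is contrasted with control power wᵀR_c w probed with the
same weights against the band's common control window. Contrast types:
difference, percent, dB, pseudo-F. Cells are independent and
deterministic, so split jobs merge bit-identically; cells whose active
covariance exceeds the condition threshold are stored as NaN with a
per-beam count, never as silent zeros. Window-length guidance (≥ 2
periods of the band's low edge) is enforced as a warning. Note the
finite-sample bias of minimum-variance power: with few effective samples
per window (narrow band × short window) the active/control ratio of pure
noise sits a few percent below 1; the null-calibration test uses window ×
band cells with enough time-bandwidth product that the median ratio is
within [0.8, 1.25].

## Minimum-norm family

G = Σ_r L_r L_rᵀ accumulated in float64 over VOI voxels. Regularization
before inversion: (1) add a scaled sensor covariance (subject data or
room noise; PSD enforced), or (2) Tikhonov with λ = mean |off-diagonal
element| of G — a diagonal-only G yields λ = 0 and is left untouched.
The rule is recorded in the filter provenance.

MN weights are G⁻¹L_r. dSPM divides each weight column by
sqrt(wᵀR_nn w); R_nn defaults to the identity when no room-noise
covariance is supplied, and the choice is flagged in the output
parameters. sLORETA normalizes by the pseudo-inverse square root of the
resolution block L_rᵀG⁻¹L_r (silent directions excluded as above); its
power map has exactly zero localization bias for a single noiseless
source, which the tests verify exhaustively over the grid. Substituting
the regularized Gram matrix for the data covariance in the LCMV formula
reproduces the MN weights up to the per-voxel normalization — the bridge
between the adaptive and non-adaptive families — and is regression-tested.

## Statistics

**Baseline threshold (within subject).** Per voxel, the empirical null
pools baseline samples over all trials; the threshold is the (1 − α)
quantile; post-stimulus samples above it are flagged. α = 1 is honoured
degenerately (threshold −∞). Calibration on stationary noise reproduces
the nominal flagging rate.

**Wilcoxon Z.** Signed-rank statistic with zeros dropped, midranks for
ties, and the exactly matching variance Var(W⁺) = Σrᵢ²/4, so the
normal-approximated Z coincides with the Z computed from exhaustive
2ⁿ sign enumeration (asserted for n ≤ 12). Requires ≥ 5 pairs.

**Common-grid resampling.** Trilinear interpolation in grid-index space;
target voxels outside the source volume are NaN; disjoint volumes are an
error. Trilinearity makes affine fields exact, which the tests use.

**SnPM.** Pseudo-t = mean / sqrt(smoothed variance / N). Only the
variance map is smoothed (3-D Gaussian, FWHM default 20 mm, truncated at
4σ, NaN voxels excluded from kernel normalization); smoothing the mean
too is an option, off by default. Sign-flip permutations: exhaustive 2^N
when 2^N ≤ the permutation budget (default 2¹⁴), otherwise unique sampled
patterns always containing the identity. The max (and min) pseudo-t over
voxels and windows is recorded separately per frequency band; corrected
p = #{permutations whose band max ≥ observed}/total, so the smallest
attainable p is 1/n_perm and p is monotone in the statistic. Two-sided
mode (default) compares |t| against the per-permutation max of |t|; note
that with sign-flip nulls the two-sided distribution pairs each pattern
with its negation, which halves the effective resolution at small N — the
calibration analysis in the acceptance suite therefore exercises the
one-sided max-statistic mode, whose level is exact (empirically 0.04–0.05
at N = 6 with 64 exhaustive permutations). SnPM requires N ≥ 5 subjects;
the 2^N pattern rule itself is exposed (and tested) separately via
`sign_flip_patterns`.

## Connectivity

Virtual electrodes come from scalar spatial filters; external reference
channels (e.g. rectified EMG) can join the signal set. Cross-spectra are
Welch estimates: per trial, mean-removed Hann-windowed segments (default
0.5 s, 50% overlap), FFT, averaged over segments and trials; at least two
averaging units are required for coherence to be defined. Coherency
C_xy = S_xy/√(S_xx S_yy); band values are means over the band's bins of
|C| and Im C respectively. Imaginary coherence is the volume-conduction-
robust metric: any instantaneous real mixture of one source has purely
real coherency, so Im C → 0 with averaging while |C| stays near 1 — both
verified empirically at 200 trials. Envelope correlation band-passes
inside the operation (4th-order zero-phase Butterworth), takes the
analytic-signal amplitude per trial, trims one cycle of the band's low
edge at each epoch end (the filter/Hilbert transient region), and
averages per-trial Pearson correlations. Whole-brain maps are computed in
deterministic chunks; a generic trial-shuffle permutation null is
provided and labelled as such — no calibrated parametric test for
coupling is claimed.

## Simulator

Sensor data are y(t) = Σ L_r q_r(t) + brain noise + white sensor noise.
Waveforms: evoked Gabor pulses (phase-locked, optional latency jitter),
induced bursts (per-trial random phase, cosine-tapered edges — they
vanish from the average but raise band power), and amplitude-modulated
carriers whose low-pass Gaussian envelopes can be coupled across dipoles
to a target correlation. Brain noise is a set of random tangential
dipoles (default 200 in the API; the test scenarios use 30–50 to keep
runtimes short) with 1/f-shaped spectra, giving a realistic full-rank
spatially structured covariance; white sensor noise is added on top. When
a target SNR is requested, the total noise is rescaled so that RMS
signal / RMS noise over a stated window, pooled over channels, matches
it; the realized value is stored in the ground truth. All randomness
flows from one seed; replays are bitwise identical. Correlated evoked
pairs mix a Gabor atom with its exactly orthogonalized quadrature, so the
sample correlation equals the target (c = 1 gives identical waveforms —
the classic beamformer failure mode). Group maps are effect + per-voxel
Gaussian subject deviation + measurement noise; a zero effect gives an
exactly sign-symmetric null for FWE calibration.

What the simulator does *not* emulate: realistic head geometry and coil
arrays, physiological artifacts (cardiac, ocular, muscle), sensor drift
and environmental interference, inter-subject anatomical variability, or
non-stationary background spectra. Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions, not
performance on any particular real recording.

## Problem sizes and defaults

The test and acceptance scenarios use 24 point magnetometers, a 9 cm
sphere, 1 cm grids of ~100 voxels (5 mm / ~930 voxels for the bilateral
suppression scenario), 40–100 trials, and 200–250 Hz sampling — sizes
chosen so every property, including the 50-run localization studies and
the 200-replicate FWE calibration, is reproducible in about a minute on a
single CPU. Defaults a user should know: Tikhonov λ = 0.001 for scan
covariances in the examples, 0.05 inside the TFBF plan; condition-number
cutoff 1e12 before a voxel/cell is flagged; SSI 20 splits; SnPM FWHM
20 mm and 2¹⁴ permutation budget; Welch 0.5 s Hann segments with 50%
overlap; suppression-zone energy 99%.

## Known limitations

No BEM/FEM or realistic-geometry forward models (import of externally
computed lead fields is the intended route); no MRI coregistration or
spatial normalization (group inputs are assumed in one coordinate frame);
no vendor raw-format readers; minimum-norm orientation handling is
vector-or-fixed (no cortical-surface constraints); the sampled-permutation
branch of SnPM draws patterns without replacement but does not
de-duplicate against sign symmetry; connectivity offers no orthogonalized
envelope variants.
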