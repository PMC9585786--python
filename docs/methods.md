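# Methods

`natriq` implements a quantitative sodium (²³Na) MRI analysis chain for calf
muscle at 7 T — acquisition simulation, field and partial-volume corrections,
phantom-calibrated tissue sodium concentration (TSC), and repeatability
statistics — together with a digital phantom that makes every stage testable
without scanner data. This note documents the models, the defaults and why
they were chosen, and what the synthetic tests do and do not demonstrate.

## Acquisition model

**Trajectory.** The sodium acquisition is a density-adapted 3D radial
projection readout (DA-3DPR): center-out spokes whose gradient is shaped so
that beyond a transition radius `k0` the sampled density falls as k⁻²
(constant samples per unit k-space volume). Radial position is linear in
time up to `k0 = t0_fraction·kmax` and follows
`k(t) = (k0³ + 3k0²·g·(t−t0))^(1/3)` beyond it, with `g` continuous at the
transition. On a unit readout this fixes `t0 = 3f³/(1+2f³)` for
`f = t0_fraction`. Spoke directions come from a golden-means spherical
spiral (deterministic, quasi-uniform). `t0_fraction` defaults to 0.25; the
pulse-sequence hardware constraints that set it on a scanner are not
modeled, so it is configuration, not physics.

The default samples-per-spoke enforces radial Nyquist at the maximum
gradient: the largest radial step `(k0/t0)/n` must not exceed the grid
spacing `2·kmax/matrix`, giving `n ≥ matrix·(1+2f³)/(6f²)` (≈ 2.9× matrix at
f = 0.25). Undersampling this produces low-frequency ripple rings in the
PSF that corrupt every downstream quantity — this is the single most
important numerical constraint in the module.

**Gridding.** Reconstruction is density-compensated Kaiser–Bessel gridding
(kernel width 4, oversampling 2, Beatty shape parameter), with image-domain
deapodization and scaling matched to the conjugate-phase DFT sum. Density
compensation uses the exact per-sample shell volume `(k_out³−k_in³)/3`,
which is strictly positive including at the k-space origin. An optional
radial Hann window (`kspace_filter="hann"`, rolling off from 0.5·kmax) is
used by the simulator and PSF path: at the protocol's ≈0.2× angular Nyquist
sampling (10,000 spokes at matrix 128, and the same ratio at desk scale)
the unwindowed PSF carries oscillating streak mass at high k that makes its
spatial integral ill-conditioned. The DFT-oracle tests run with the filter
off; a width-4 gridding kernel reproduces the direct DFT to ≈0.1% RMS,
which is why oracle comparisons are asserted at the 1% level rather than at
machine precision.

**PSF.** The PSF is the reconstruction of unit k-space data, optionally
phase-modulated by off-resonance over the per-sample readout times and
damped by a bi-exponential T2* envelope (cohort-mean muscle values by
default, mirroring how the in-vivo PSF was generated for partial-volume
correction). Normalization is to unit sum so mask convolution preserves
mass. Two extents exist: the nominal-FOV kernel (default; self-consistent
for everything inside the pipeline) and a `full_extent` kernel on the 2×
oversampled field that captures the undersampling halo — required when
comparing image-domain blurring against actual k-space round trips, which
agree to <1% RMS once the same kernel extent and normalization are used.
A dense, unwindowed acquisition gives a PSF FWHM of ≈1.44 voxels, the
transform of a uniformly weighted k-space ball; the nominal resolution is
therefore not the FWHM, and PSF tests compare against this physical limit.

## Digital phantom

The phantom is schematic, not anatomical: an extruded elliptical calf with
three muscle compartments (GM ≈ 14%, TA ≈ 11%, S ≈ 21% of muscle, remainder
"other"), four calibration tubes at 15.4/30.8/46.2/61.6 mmol/L on a
peripheral ring, and a separate homogeneous 61.6 mmol/L cylinder scenario
that fills the coil (covering the tube radius). Only region statistics
matter downstream, which is what the schematic geometry preserves.

Ground truths: healthy TSC {GM 19.9, TA 13.8, S 12.6} mmol/L, Addison's
{10.2, 8.4, 7.2} mmol/L; muscle relaxation T1 {25.9, 27.6, 28.2} ms,
T2s* {3.6, 3.2, 3.0} ms, T2l* {12.9, 12.8, 12.9} ms, Fs/Fl = 60/40. The
agarose phantom material is modeled with T1 27 ms (copper doping matches it
to muscle) but deliberately different T2* (5/16 ms, Fs 40%) so the
relaxation-difference correction does real work in tests. B0 is a random
low-order polynomial scaled to ±50 Hz, B1⁺ similarly within 0.8–1.2;
susceptibility-induced field structure, motion, flow, and full spin-3/2
Bloch dynamics are not modeled.

The forward signal is
`TSC·sin(α)·(1−exp(−TR/T1))·[(Fs/100)e^(−TE/T2s*)+(1−Fs/100)e^(−TE/T2l*)]`,
with the signed factor `(1−2e^(−TI/T1))` replacing saturation for
inversion-recovery series. Complex Gaussian noise is added per coil, so
magnitude images are Rician; the fit offset parameter absorbs the resulting
floor. The default noise level is calibrated at run time so the healthy
calf's sodium-protocol muscle SNR is 16, the cohort value; this calibration
is a function of the phantom and PSF, not a stored constant. Every
stochastic operation takes an explicit seed (pipeline default 20220719);
identical seeds give bitwise-identical series.

Two forward modes exist: `image_psf` (ideal volume convolved with the
protocol PSF — fast, used by the pipeline) and `kspace` (forward-sampled on
the trajectory and gridded back, k-space samples retained for off-resonance
work). They cross-validate each other to <1% RMS on noiseless phantoms.

## Corrections

**Coil combination** is 3D Walsh-style adaptive combine: dominant
eigenvectors of local coil covariance over overlapping blocks (8 voxels,
placed every block/interp_factor voxels, defaults 8 and 2), phase-referenced
to the first coil and trilinearly interpolated. **SNR maps** use the
multiple-replica approach: noise matching the noise-only scans' statistics
is repeatedly added, each copy reconstructed, and SNR = mean/sd per voxel.

**B0** comes from the dual-echo phase difference (TEs 0.60/1.60 ms), valid
to ±1/(2ΔTE) = ±500 Hz before wrapping. **B1⁺** uses the phase-sensitive
composite pulse (nominal 180° about x then 90° about y): the transverse
phase after the composite rotation is strictly monotone in the actual flip
over (10°, 170°) and spans less than 2π, so a tabulated inversion is
unambiguous; voxels outside that branch are flagged invalid. Off-resonance
correction reconstructs the k-space data at (by default 20) demodulation
frequencies spanning the B0 range and assembles the image by nearest-bin
selection per voxel.

**Intensity correction** transfers shading from the homogeneous cylinder,
which is simulated with the same seed as the subject because both are
scanned in the same coil and shim — the transfer premise. The gain is
(expected)/(smoothed observed) where the expectation is the cylinder's own
geometry blurred by the protocol PSF; normalizing against a flat nominal
instead would fold the cylinder's rim rolloff into the gains exactly where
the calibration tubes sit. The cylinder gain already contains the combined
transmit/receive B1 shading, so no separate sin(α) factor is applied on
top of it (applying both would correct twice); B1 maps serve validity
masking and reporting. Gaussian smoothing of the factors uses sd 2 voxels.

## Partial-volume correction (GTM)

Region-spread functions are compartment masks linearly convolved with the
unit-sum PSF; the GTM weight `ω[j,i]` is the mean of RSF_i over ROI j, and
observed ROI means `b` are corrected by solving `ω·c = b` (least squares,
condition number reported, >10⁶ rejected). For noiseless piecewise-constant
images this inversion is exact for any PSF — provided every signal-carrying
structure is a compartment. That is why the pipeline includes the
calibration tubes in the matrix by default: at ≈0.2× Nyquist the PSF halo
exchanges signal between tubes and muscle across the whole FOV, and leaving
the tubes outside the system breaks the end-to-end recovery. A bypass
(`include_tubes_in_gtm=False`) reproduces the workflow in which tubes are
never segmented. A 3-slice mode restricts ROI means to chosen slices while
keeping RSFs 3D.

## Quantification

Calibration is an ordinary least-squares line of corrected tube intensity
versus concentration (intercept free by default, absorbing any residual
floor; a through-origin switch exists). TSC is
`(I_tissue/f_tissue)/(I_ref/f_phantom)·25 mmol/L`, where `I_ref` is the
curve-predicted intensity at the 25 mmol/L reference and `f` is the
steady-state relaxation factor `(1−e^(−TR/T1))·[biexponential at TE]`.
Tissue factors use the cohort-mean relaxation values by default (per-muscle
override available). The whole chain is invariant to a global intensity
scale, which the tests assert.

At matrix 64, SNR 16, the full chain recovers the generative truths within
0.5% (healthy and Addison's scenarios). The before/after-correction TSC gap
is {GM ≈ 24%, TA ≈ 30%, S ≈ 39%} — larger for the soleus than the 12–23%
range measured in vivo, because the schematic geometry at desk matrix has
stronger partial-volume mixing than real anatomy at matrix 128; the
across-muscle mean (~31%) is the quantity checked against that range.

## Relaxometry

Fitting is ROI-by-ROI on mean signal curves (ROI geometry fixed on the
lowest-TE image and reused), by bounded Levenberg–Marquardt least squares
with 8 jittered multi-starts (fixed sub-seed), ftol 1e-10, 500 iterations.
T1 uses the magnitude IR model with T1 initialized from the signal-minimum
TI via TI_null/ln 2; T2* uses the five-parameter bi-exponential with
amplitudes ≥ 0 and 0.1 ≤ T2s* ≤ T2l* ≤ 100 ms, components ordered after the
fit. Degeneracy flags fire when the two time constants approach (ratio
> 0.9) or one amplitude carries <2% of the total; constant (offset-only)
input returns a non-converged T1 fit. The short component is intrinsically
the hardest, consistent with the wide per-subject spread the in-vivo table
shows for that parameter. A note on attainable precision: the Cramér–Rao
bound for the five-parameter model at the 20 protocol echoes gives a
relative sd of T2l* near 75% of a single curve whose per-point SNR is 30 —
no fitter can do better — so useful precision comes entirely from ROI
averaging: a 200-voxel ROI at image SNR 30 yields per-curve SNR ≈ 420,
where median T1 and T2l* errors drop below 5% (the recovery study's
condition).

## Statistics

ICC uses the two-way subjects × sessions decomposition; all four variants
(A1, Ak, C1, Ck) are computed with F-based confidence intervals (exact for
consistency, McGraw–Wong approximation for absolute agreement) and are
cross-checked against pingouin. The reported default is Ck — average
measures, consistency: although the study describes a two-way
absolute-agreement model, the printed coefficients (0.784/0.818/0.807) are
exactly the Ck values of the TSC table, while Ak gives ≈0.80 throughout;
both are available and the discrepancy is surfaced rather than hidden. The
computed CIs also suggest the printed CI columns were shifted by one muscle
(the TA interval matches the printed GM one, etc.), so CIs are computed but
not matched against the print.

The exact nonparametric tests enumerate their null distributions by dynamic
programming on doubled midranks (so ties are exact, not approximated):
signed-rank over all 2ⁿ sign assignments via the rank generating
polynomial; rank-sum over all C(n₁+n₂, n₂) assignments via a subset-sum DP;
Friedman over all within-subject rank permutations via a joint
column-sum DP. Asymptotic (tie-corrected normal / chi-square) p-values are
reported alongside. Per-subject values entering Friedman and the pairwise
signed-rank comparisons are session means (M1–M3); a single-session mode is
the documented alternative. Bland–Altman limits are mean ± 1.96 sd of
paired differences. Display rounding is half-away-from-zero, one decimal
for concentrations and three for ICC.

## Problem sizes and limitations

Default simulations run at matrix 64 with spokes scaled by (matrix/128)² to
preserve the protocol's angular sampling ratio; unit and oracle tests use
16³–48³ problems. Passing synthetic tests demonstrate internal consistency
of the full chain under the stated noise and field models — they do not
demonstrate robustness to real anatomy, registration error, motion,
residual fat signal, or deviations of tissue relaxation from the assumed
cohort means, all of which the in-vivo workflow must face. The printed
Friedman P = 0.0005 and pairwise P = 0.018 of the source tables are not
reproducible from the table values under standard exact or asymptotic
conventions (our exact enumeration gives smaller values); tests therefore
assert significance thresholds, not those specific p-values.
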