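# Methods

## The phantom and its forward model

The object is an additive composition of ellipses, the standard
analytic-phantom construction: the image is Σᵢ Iᵢ·χ(Eᵢ(t)) and its 2-D
Fourier transform is the matching sum of closed-form terms

F(k) = I · π a b · 2 J₁(2πρ)/(2πρ) · exp(−2πi k·c),

with ρ the frequency radius mapped through the ellipse's semi-axes and
rotation, J₁ the first-order Bessel function, and the ρ → 0 limit equal
to I times the ellipse area. Compartments that are not simply connected
(myocardial shells) are built additively: outer ellipse at +myocardial
intensity, cavity carved at −myocardial intensity, blood pool added on
top. Each ellipse carries a signed `volume_weight` so exact compartment
areas (and hence volumes, EF, mass) follow from π a b sums.

The default phantom is a short-axis mouse thorax: chest-wall ellipse
(intensity 0.25), a liver proxy below the heart (0.60 absolute), LV and
RV with bright-blood contrast (blood 1.0, myocardium 0.55). The LV
cavity contracts from r = 1.5 mm to r = 0.8 mm, fixing the ground-truth
ejection fraction at 1 − (0.8/1.5)² = 71.6%, in the range reported for
healthy mice by cine CMR. Five 1-mm slices with mild apex-to-base
tapering (scale factors 0.85–1.0) are the default; nine are supported.

### Motion model

* **Cardiac** (period 0.125 s = 480 bpm): semi-axes interpolate linearly
  between end-diastolic and end-systolic values along a raised-cosine
  contraction waveform with a systolic fraction of 0.4 (zero at phase 0,
  one at phase 0.4, C¹-smooth). No waveform is prescribed by the imaging
  physics; any smooth periodic function with a distinct ED/ES pair
  behaves equivalently.
* **Respiratory** (period 1 s = 60 breaths/min, anesthetized): a
  raised-cosine inspiration burst occupying 30% of the cycle followed by
  a quiescent end-expiration plateau. It displaces structures in-plane
  (heart 0.25 mm, liver 0.35 mm cranio-caudal) **and** modulates the
  intensity of diaphragm-adjacent tissue (liver −25%, chest −4%, heart
  −3% at peak inspiration). The intensity term is essential and
  deliberate: the k-space origin is mathematically invariant under pure
  in-plane translation, so a k = 0 navigator would otherwise record no
  respiration at all. Physically it stands in for through-plane motion
  of tissue across the 1-mm slice — the mechanism by which real
  self-gating sees breathing. It is a 2-D surrogate, not a model of the
  slice profile.

What the phantom does **not** emulate: through-plane (3-D) motion and
slice-profile effects, T₁/T₂ relaxation and flip-angle dynamics, coil
sensitivity, arrhythmia, susceptibility gradients. Recovery tests
therefore demonstrate the correctness of the processing chain under
ideal periodic physiology, not robustness to real-animal variability.

## Acquisition simulation

Spokes are center-out radial rays: sample j of a spoke at angle θ sits
at k = (j/FOV)·(cos θ, sin θ), j = 0 … matrix/2 − 1, i.e. uniform radial
steps of 1/FOV up to just below the Nyquist radius matrix/(2·FOV). The
reference protocol (TE 0.314 ms, TR 6.2 ms, matrix 156, FOV 20 mm, 246
projections at constant angular increment, polar undersampling 2, 200
movie cycles) gives 49 200 spokes and 305.04 s per slice. Each spoke
samples the analytic transform at the single time of its k = 0 sample:
the 0.78 ms readout is ~160× shorter than the cardiac period, so
intra-spoke motion is neglected. Complex white Gaussian noise (i.i.d.
per channel) is added; slices are acquired sequentially with independent
noise substreams spawned from one seed.

Two spoke orderings are implemented. The default `sweep` repeats the
full 246-angle sweep 200 times; because the 1.525 s sweep period is
incommensurate with the 0.125 s cardiac period, every cardiac bin
accumulates near-uniform angular coverage. `repeat` (dwell on each angle
for all movie cycles) is available for comparison.

**Noise calibration.** `navigator_sigma_for_snr` defines SNR as the
cardiac modulation amplitude of the noiseless k = 0 navigator (half its
peak-to-peak excursion over a cycle) divided by the per-channel noise
sigma. The default pipeline condition is navigator SNR 10.

**Flow-phase emulation.** Ellipses tagged with a flow velocity v (blood
pools: LV 60 mm/s, RV 40 mm/s) acquire an extra phase 2π·c_flow·v·TE
before summation. This is a deliberately minimal surrogate for
flow-induced phase errors: it reproduces the qualitative signature that
reconstruction error against an artifact-free reference grows
monotonically with TE over 0.314–3 ms (with the default c_flow = 0.002
per (mm/s)·ms the phase stays below π across that range, so monotonicity
is guaranteed), and nothing more. Off by default.

Gradient-ramp sampling, half-pulse excitation, Bloch dynamics and the
Cartesian comparison sequence are not simulated; the Cartesian preset
exists only for protocol arithmetic (scan time, pixel size).

## Self-gating

The navigator is |data[:, 0]| per slice, sampled at 1000/TR =
161.29 Hz. Processing: (1) subtract a 2-s sliding-mean baseline (≥ 2
respiratory periods); (2) zero-phase 4th-order Butterworth band-passes
into a respiratory band (0.5–3 Hz) and a cardiac band (4–26 Hz); (3)
estimate each rate as the quadratically-interpolated peak of a
zero-padded periodogram restricted to its band (flat signals raise an
error rather than return a number); (4) detect cardiac peaks with
minimum separation 0.6/rate, refine peak times by parabolic
interpolation, and assign each spoke the phase (t − pₖ)/(pₖ₊₁ − pₖ);
spokes outside the first/last peak are extrapolated with the median beat
interval and counted as edge-extrapolated beyond 1.5 intervals; (5)
locate the end-expiration plateau as the histogram mode of the
respiratory signal and accept the 70% of spokes closest to it.

The cardiac band's upper edge (26 Hz) deliberately admits the 2nd/3rd
harmonics of a ~8 Hz heartbeat. With a fundamental-only band the
asymmetric contraction waveform shifts the filtered signal's maxima to
~0.05 of a cycle before true end-diastole — a systematic phase bias;
retaining the harmonics sharpens the ED peak and reduces the bias to
~0.01. The band stays clear of the respiratory band and of the 80.6 Hz
Nyquist limit, and brackets mouse heart rates (400–900 bpm).

All gating is deterministic and scale-invariant (no absolute
thresholds), so multiplying the navigator by any constant yields an
identical gating result. Zero-phase filtering guarantees the derived
phases are not delayed relative to spoke times.

Measured at the reference conditions (49 200 spokes/slice, navigator
SNR 10): both rates recovered within 0.1%, mean absolute circular phase
error ≈ 0.016.

## Reconstruction

Accepted spokes are binned by frame = ⌊phase · n_frames⌋ (default 16
frames). Each frame is reconstructed by convolution gridding:

* **Density compensation**: ramp weights wⱼ ∝ |kⱼ| · Δk · 2π/n_spokes —
  the area of the annular sector each sample owns — so the weighted
  adjoint approximates the continuous inverse Fourier integral and frame
  amplitude is independent of spoke count. The k = 0 sample is shared by
  every spoke in the frame; its weight |k₁|/8 makes the summed center
  weight equal the area of the center disc of radius Δk/2 (a /4 constant
  would double-count it and add a measurable constant offset to the
  image).
* **Kernel**: separable Kaiser-Bessel, width 4 grid cells, oversampling
  2, shape parameter from the standard width/oversampling formula
  (β = π√((W/α)²(α−0.5)² − 0.8) ≈ 9.0). Samples are convolved onto the
  312² oversampled grid (periodic wrap at the edge).
* **Transform**: inverse FFT arranged so image(x) = Σₘ grid(m)·exp(+2πi
  kₘ·x) at pixel centers x = (n − matrix/2)·FOV/matrix; central crop;
  deapodization by the kernel's analytic transform evaluated on the
  image grid; magnitude.

The same coordinate conventions are used by a brute-force adjoint NDFT
(`adjoint_ndft_oracle`, capped at matrix 64), so gridder and oracle
agree to NRMSE < 0.001 on random data — the oracle is the independent
correctness reference, never the reconstruction path.

A fully-sampled static disk at matrix 156 reconstructs to NRMSE 0.057
against the rasterized truth; the circular-truncation Gibbs floor alone
is 0.053 at this matrix, so the gridder operates within ~0.004 of the
physical limit. The full-thorax phantom additionally shows faint
sparse-sampling background rings near the FOV edge (the 17-mm chest is
large relative to the 20-mm radial FOV); they sit away from the heart
and do not measurably bias quantification. No per-frame Voronoi density
correction is applied — under `sweep` ordering the per-frame angle
distribution is near-uniform; this is an extension point.

## Quantification

CNR = (mean blood − mean myocardium)/σ_noise with the noise taken from
object-free background pixels. Volumes are slice sums of segmented areas
times slice thickness (µl); SV/EF/CO and mass (1.05 mg/µl) follow the
definitions above, and the stored report satisfies these identities
exactly by construction. Teichholz (V = 7/(2.4 + D)·D³, mm → µl by
default, cm → ml behind a flag) and Simpson method-of-disks
(Σ π/4·aᵢ·bᵢ·h) estimators are provided for echo-side comparisons.

Segmentation for recovery tests is threshold-based and ground-truth
assisted: the phantom's known geometry at each frame's phase seeds a
dilated region of interest and supplies core samples of the blood and
myocardial intensity levels; the blood threshold is their midpoint, the
myocardial band lies between the surrounding-tissue level and that
threshold. ED and ES frames are those with maximal/minimal thresholded
LV blood area. This is an instrument for validating the pipeline — the
reference procedure is manual tracing, and automated segmentation is
explicitly out of scope, so recovery results should not be read as
segmentation performance.

End-to-end at the reference conditions (matrix 156, 5 slices, 16
frames, seed 1): recovered LV EF 70.8% vs 71.6% truth, SV 21.9 vs
22.4 µl, mass 58.8 vs 58.5 mg.

## Numerical and design choices

* Problem sizes: the default pipeline runs 5 slices (configurable to the
  full 9); validation suites use the full 49 200 spokes per slice at
  matrix 156, with shortened (30–40 movie cycle) variants where only
  mechanism, not statistical power, is under test.
* jinc evaluated as 2J₁(z)/z with a series branch below |z| = 1e−8;
  k = 0 therefore returns exactly intensity × area.
* Peak/rate estimation uses log-power parabolic interpolation clipped to
  ±½ bin; degenerate inputs (flat signal, < 2 peaks, empty masks, zero
  noise std, ESV ≥ EDV) raise errors rather than produce numbers.
* A constant respiratory signal with accept_fraction < 1 accepts all
  spokes with a warning (nothing to gate on).
* Empty cardiac frames abort reconstruction with the frame and slice
  named; rejected spokes are dropped, never phase-shifted.
* Determinism: one integer seed drives per-slice noise substreams; all
  later stages are seed-free, so every stage is bit-reproducible.
* Serialization: phantoms and pipeline configs as YAML; spokes as HDF5
  with the protocol in a JSON attribute; cine as NIfTI-1 (pixdim from
  FOV/matrix and slice thickness) with frame phases in a JSON sidecar;
  gating as CSV; reports as JSON.

## Known limitations

2-D only; periodic motion without beat-to-beat variability; respiration
enters the navigator through a surrogate intensity term rather than a
slice-profile model; the flow-phase term is qualitative; segmentation
requires ground-truth seeding and is not applicable to real data; the
Cartesian comparison sequence is represented by protocol arithmetic
only.
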