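# Methods

## Scope and model

`ptychoplan` treats a 4D-STEM ptychography acquisition as three parameter
groups — electron beam (voltage, convergence semi-angle α, defocus Δf,
current, focused-probe diameter d0), scan raster (step ΔR, grid,
dwell time, skip), detector (pixel count, pitch, binning, padding,
effective camera length L, pumping-aperture angle ceiling) — and derives
all design figures from closed-form optics, then validates them with a
synthetic-data / reference-reconstruction loop.

Unit conventions: voltages kV, angles mrad, wavelength pm, real-space
lengths Å (defocus nm, detector pitch µm, camera length cm), current pA,
dwell µs, dose e/Å². Every public function documents its units in its
signature names (`alpha_mrad`, `step_A`, …); conversions are exact scalar
factors applied at function entry. An SI-only internal layer was
considered and rejected as adding a second unit system without changing
any result.

## Derived geometry and conventions

* Wavelength: relativistic de Broglie formula with CODATA constants
  (scipy.constants).
* Angular pitch: Δθ = p_eff/L in the small-angle approximation, with
  p_eff = pitch × binning. The maximum detected angle θ = M·Δθ is taken
  at the midpoint of the detector edge (M = half-width in effective
  pixels); corners are ignored. This convention reproduces the worked
  79.8 mrad coverage of a 192²-pixel detector and is used consistently in
  the checks. θ is clipped to the pumping-aperture restriction when one
  is calibrated.
* Dose: electrons/position = I·t/e; dose = electrons/ΔR_used², with
  ΔR_used = ΔR·(skip+1). Skipping therefore divides dose by (skip+1)²
  exactly. (A published low-dose series quotes 231 e/Å² where this
  arithmetic gives ≈236 e/Å² from the same inputs — an implied ~1 %
  scan-step calibration factor that is not recoverable from the printed
  parameters; the package always reports the computed value.)
* Defocus is a magnitude (the sign does not affect any intensity used
  here). The geometric probe diameter defaults to the additive
  composition d0 + 2·Δf·tan α — the conservative, larger estimate;
  quadrature composition is available as an option. Consistently, the
  maximum defocus bound subtracts d0: Δf_max = (d_probe_max − d0)/(2 tan α),
  reducing to the pure geometric form at d0 = 0.
* Reconstruction pixel for iterative methods is reported as Pix_ITR = λ/θ
  (θ the edge half-angle), the convention design tools quote. The
  FFT-based simulator and ePIE necessarily work on the natural grid pitch
  λ/(2θ) = D_ψ/n_k (n_k samples across the probe window λ/Δθ); the two
  differ by the factor 2 between half-width and full-width counting.
  Detector zero-padding enters as a ≥ 1 factor shrinking Pix_ITR; it does
  not change Δθ.
* All sampling formulas use exact trigonometric forms; small-angle
  versions appear only as oracles in the tests.
* Scan grids are isotropic (ΔR_x = ΔR_y); skip applies identically to
  both axes.

## SSB transfer function

The analytic single-side-band CTF counts the net area of ONE sideband:
the lens-shaped overlap of the unit-radius (α) bright-field disk with the
disk displaced by ω = Q/α, minus the triple-overlap region shared with
the opposite (−ω) disk. The triple overlap equals the two-disk lens at
separation 2ω (it lies entirely inside the central disk) and vanishes for
ω ≥ 1. Closed forms use the circle-lens area 2·cos⁻¹(s/2) − (s/2)√(4−s²).
The curve's true argmax is ω ≈ 0.894 (0.9 to plotting precision); the
"peak" normalization scales the ω = 0.9 value to 1. Both-sidebands
counting would double every value and cancel in any normalization. The
plot normalization used in published figures is not stated anywhere we
know of, so both `max_one` and `area_ratio` (area/πα²) are exposed.

## Checks engine

Verdicts are three-state. "Fixed" method limits (SSB: ≥ 1α coverage,
≥ 4-pixel BF disk) fail hard; editable limits warn within 10 % of their
threshold, so a CLI exit code can distinguish comfortable from marginal
plans. Two-sided or derived conditions are mapped to signed margins so
every rule is a one-sided bound; tightening any threshold can then never
turn a fail into a pass (tested). The "pattern recovery level" is a
user-set factor (default 1) checked against Ŝ; the "low count area"
coverage ceiling defaults to 6α and is configurable, as no sharper
quantitative definition exists. Note that a focused, finely-stepped plan
legitimately fails the resolution-gain rule (ΔR_used/Pix_ITR ≥ 1): with
ΔR below the reconstruction pixel the image has fewer pixels than scan
positions. Direct-method acquisitions oversample real space by design;
the rule is an ITR-efficiency criterion, not an error in such plans.

## Probe simulation and illumination

Probes are hard-aperture, fully coherent, with defocus as the only
aberration: ψ = IFFT[A(k)·e^(−iπλΔf k²)], normalized to unit total
intensity. Parameter combinations that undersample the aperture (< 4
reciprocal samples across 2α) or alias it (α beyond grid Nyquist) raise
an explicit error naming the violated bound. The d59 probe diameter is
the smallest circle centred on the intensity centroid containing 59 % of
the intensity (the vendor definition of probe size); for a defocused
hard-aperture probe this sits near √0.59 ≈ 0.77 of the geometric cone
diameter, the top-hat encircled-energy limit, which the tests use as the
oracle. Illumination maps place per-position-normalized probe intensities
on the scan grid (offsets rounded to the probe grid pitch). Uniformity
U = 100·I_min/I_max is evaluated on the interior of the scanned bounding
box at least one probe diameter (d59 by default, overridable) from its
edges; U is a documented, swappable strategy because no standard
definition exists — no numerical uniformity value is asserted against
published numbers.

## Synthetic 4D-STEM data

Forward model: single multiplicative thin phase object, exit wave =
probe × e^{iφ}, far-field intensity = |FFT|² on the centred detector grid
(DC at index n_k//2). The object must be sampled on the probe-grid pitch;
scan offsets are split into an integer-pixel patch shift (periodic wrap)
and a sub-pixel remainder applied to the probe as a reciprocal-space
phase ramp, so arbitrary steps are exact. Noiseless patterns sum to
exactly 1 per position (unitary FFT); stored as float32, so conservation
holds to ~10⁻⁷ relative in storage. A probe whose geometric diameter
exceeds half the probe window triggers a recorded warning (aliasing), not
a silent failure. Shot noise distributes a fixed electron budget
(I·t/e, rounded) multinomially over the pixels of each pattern — totals
are conserved per position by construction — with a per-position
generator seeded as (seed, iy, ix) for evaluation-order independence and
bit reproducibility. Binning block-sums detector pixels (counts
conserved, Δθ scaled); skipping keeps every (skip+1)-th position and
rescales step and dose metadata. The two operators commute. Weak-phase
objects used in tests keep |φ| ≤ 0.5 rad.

HDF5 layout (version 1): dataset `/data` shaped (scan_y, scan_x, k_y,
k_x); root attributes `step_A`, `dtheta_mrad`, `lambda_pm`, `alpha_mrad`,
`defocus_nm`, optional `dose_e_per_A2` and `seed`.

## Reference reconstructions

**SSB.** G(k, Q) = FFT over scan position of the recorded intensities.
For each scan frequency Q the trotter masks classify detector pixel
centres against the three disks at 0 and ±Q·λ; pixels in the
triple-overlap are excluded. The estimator integrates G over the +Q
sideband minus the −Q sideband, divides by 2i·a² (a² = mean bright-field
intensity per pixel, measured from G(k, 0)) and by the analytic peak
trotter area, so a weak sinusoid of amplitude φ₀ at frequency ω is
recovered with amplitude φ₀·CTF(ω) in the peak-normalized convention; an
area-ratio normalization is available. Output grid = scan grid
(Pix_SSB = ΔR_used); steps above the λ/(2 sin 2α) bound produce a warning.
The measured transfer agrees with the closed-form curve to the
pixelation of the trotter masks (≈ 2–3 % RMS with a 10-pixel BF-disk
radius, improving with detector sampling — verified at three resolutions).

**ePIE.** Standard sequential object/probe update with modulus
replacement, periodic object on the probe-grid pitch initialized to unit
transmission, probe initialized from the dataset's aperture parameters
with a 10 % defocus error (or supplied and optionally held fixed).
Positions are visited in raster order by default; a seeded shuffle is
optional. The per-iteration RMS amplitude mismatch is recorded. Scan
offsets are rounded to the object grid; commensurate steps make this
exact.

**Numerical ITR transfer.** Isolated radially-symmetric Gaussian phase
bump (default amplitude 0.3 rad, σ = 1.5 object pixels — narrow enough
that its spectrum stays above the deconvolution floor beyond 2α),
noiseless simulation, ePIE reconstruction, Fourier division of true from
reconstructed phase with a Wiener-style floor at 10⁻³ of the peak
denominator magnitude, azimuthal average onto an ω axis (bin width 0.1).
The division errors out when the floor invalidates more than half the
samples inside the reported range (e.g. for spectrally sparse objects).
On noiseless data the resulting curve rises immediately to a plateau ≈ 1
extending past the 2α aperture limit — iterative methods' superresolution
from high-angle disk overlaps; dose-dependent decay of that tail is out
of scope (an effective reduced θ can be supplied instead).

## Problem sizes and determinism

The validation experiments are sized for a laptop-class single CPU: the
transfer study uses a 64² scan over one periodic window with a 64²
detector (BF-disk radius 10 px) and five sinusoids placed exactly on the
scan DFT grid; ePIE recovery uses a 32² scan, 64² detector, 50
iterations with the true probe held fixed; the tiny-detector study uses
4² patterns (BF disk 2 px, Ŝ = 2) over a 64² scan; the numerical ITR
curve uses a 32² scan and 30 iterations. All are deterministic: the only
randomness anywhere is the explicit Poisson/multinomial sampling and the
optional ePIE shuffle, both seeded.

## What the synthetic data do and do not show

The generator emulates weak-phase, fully coherent, aberration-free
(beyond defocus) single-slice scattering on an ideal counting detector.
It does not model thickness/multiple scattering, partial coherence,
source size, scan distortion, detector MTF, flat-field or dead pixels.
Passing tests therefore demonstrate the internal consistency of the
sampling/transfer theory and the correctness of the implementations —
not that a real instrument will achieve these bounds; on real data the
bounds are necessary, not sufficient.

## Known limitations

* Single-slice forward model only; multislice simulation and
  reconstruction are out of scope (the r_z slice-thickness bound is
  reported, not exercised).
* ePIE is the minimal engine: no mixed states, position correction,
  low-pass constraints or ML variants; heavily model-mismatched data
  (e.g. post-collection binning of fine-pixel data to 4²) can stagnate
  where production engines still converge.
* Calibration routines are pure computations on user-measured quantities;
  no peak finding on calibration images.
* The illumination-uniformity formula is a package convention (min/max
  over the interior), not a community standard.
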