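# Methods

## Optical model and its assumptions

A tissue section is treated as a single-scattering, non-depolarizing layer of
oriented birefringent fibrils: at each pixel a pure linear retarder with
optical-axis orientation ρ ∈ [0, π) and phase shift δ = 2πΔn·l/λ. The
Mueller matrix is M(ρ, δ) = Rot(2ρ)·Retarder(δ)·Rot(−2ρ); its lower-right
3×3 block is a rotation matrix, f11 = 1 and the remaining first-row/column
elements vanish. Excluded by construction: diattenuation, depolarization,
circular birefringence/optical activity, multiple scattering. Under this
model the azimuthal invariants collapse onto the phase alone:
f44 = F22;33 = cos δ and F42;43 = F24;34 = |sin δ| (the root-of-sum-of-
squares convention is used for the latter pair so that they equal |sin δ|
rather than sin²δ). These identities are asserted in the test suite at
1e−10 on randomized (ρ, δ) and provide an internal consistency check for
any reconstructed image.

Angles are radians internally (the CLI accepts degrees behind an explicit
flag); the pixel grid is 0-based row-major, with the Ox scan indexing
columns and the Oy scan indexing rows.

## Simulated measurement

The synthetic polarimeter probes each pixel with four unit-intensity states
(linear 0°, 45°, 90°, right circular) and records six ideal-analyzer
projections (0°, 45°, 90°, 135°, R, L), I = ½(S′₁ + a·S′₂..₄). Stokes
images follow from the standard differences SV1 = I0+I90, SV2 = I0−I90,
SV3 = I45−I135, SV4 = I_R−I_L, and the sixteen MM elements from the linear
combinations f_i1 = ½(SV_i⁰+SV_i⁹⁰), f_i2 = ½(SV_i⁰−SV_i⁹⁰),
f_i3 = SV_i⁴⁵−f_i1, f_i4 = SV_i^⊗−f_i1, renormalized so f11 = 1 (pixels
with no transmitted intensity are flagged invalid). The noise model is
additive Gaussian on every analyzer intensity, clipped at zero, with
standard deviation `noise_sd` in units of the probe intensity (default
0.005, a realistic CCD noise floor well below the detection tolerance).
The noise-free chain MM → intensities → Stokes → MM is the identity to
1e−9; this round trip is an acceptance test at 256×256.

## Characteristic values and scan counts

A pixel is a characteristic-value pixel when its invariant lies within
ε of the singular target (0, or ±1 with either sign accepted). ε defaults
to 0.02 in invariant units — about 1 % of the [−1, 1] range; no canonical
tolerance exists for discretized maps, and the value is configurable.
Scan profiles are per-column (Ox) or per-row (Oy) totals of masked pixels;
a cumulative-along-the-scan variant exists behind a flag but is not the
default, as the per-line total is the reading that yields a translation-
meaningful 1-D profile. Profile sums equal mask cardinality by
construction (conservation), asserted as a property test.

## Wavelet transform

The MHAT CWT is evaluated as the discrete sum
Q(a, b) = a^(−1/2) Σ_x q(x)·Ω((x−b)/a) with unit pixel quadrature over a
reflection-padded profile. Padding is 6·a_max: the integral of the MHAT
tail beyond |t| = 6 is ~1e−7, so constants are annihilated to below 1e−6
at every position, while a narrower pad (e.g. 3·a_max) leaves visible
~1e−4 residuals. Kernels are cached per (profile length, pad, scale), so
cohort-scale batches cost one matrix-vector product per scale. The default
scale grid is a ∈ {2, 4, …, min(n/4, 64)} for a length-n profile — fine
enough for the micro scan below, capped so the widest wavelet still fits
the profile. The transform is linear and translation-covariant on integer
shifts (tested), and matches a brute-force evaluation of the defining sum
to 1e−9 (acceptance test at length 512).

## Optimal-scale selection

For each scale a, the scale line Q_a(b) is summarized by Z1 (mean) and Z2
(dispersion). The search is two-stage: a macro scan over multiples of 10
locates the first interval where the monotone rise of Z2 terminates
(ΔZ2 ≤ 0); that interval, widened by one macro step on the left so it
brackets the dispersion peak, is re-scanned at micro step 2, and A* is the
micro-grid scale with maximal Z2 (Z1 breaks exact ties). The macro/micro
steps (10 / 2) are the conventional choice for camera-scale profiles.

Design note: an alternative reading of the stopping rule — "advance while
ΔZ ≤ 0, take the first rising interval", then maximize the *increment*
ΔZ — anchors A* at the steepest rise of the dispersion curve rather than
at its peak. A matched-filter argument (and the package's own tests) show
the dispersion of Q_a(b) for a single-scale profile peaks at ≈1.12× the
injected scale, while the steepest rise sits well below it; maximizing Z2
inside the bracketed interval is the variant that actually recovers an
injected dominant scale to within one micro step, so it is the one
implemented. When the dispersion never stops rising on the macro grid, or
the field is degenerate (constant profile), the selection falls back to
the global argmax of the dispersion increments and sets a `fallback` flag.
For cohorts, the Z curves are averaged across samples before selection
(`select_scale_for_fields`), giving one A* per analysis without label
leakage.

## Statistics and classification

Z1 is the mean, Z2 the population variance ("dispersion" D is reported as
the variance, not its square root — configurable), Z3 = m₃/Z2^{3/2} and
Z4 = m₄/Z2² − 3, undefined (flagged) for constant input. Group comparison
uses the two-sided Mann–Whitney rank test (robust at n = 36 per group; no
distributional claims are made about count features). Per-sample diagnosis
for Se/Sp/Ac uses, by default, the midpoint of the two group means as
threshold with polarity from the order of the means, evaluated
leave-one-out so a sample never informs its own threshold; an in-sample
"optimal-threshold" rule is available behind a flag. Degenerate features
(identical constant in both groups) are flagged and scored Ac = 50. No
multiple-testing correction is applied by default to the per-feature
p-values; the tables report raw p.

## Phantom design — what it emulates and what it does not

`generate_phantom` builds: (i) a smooth random orientation field ρ as the
half-angle of a Gaussian-filtered random director, with 1/e correlation
length ≈ `domain_scale`; (ii) a phase field δ = clip(δ̄ + σ_δ·z, 0, π)
sharing the domain structure (the clip keeps δ = π/2, the C condition,
interior); (iii) near-isotropic patches covering `isotropic_fraction` of
the area at characteristic size `patch_scale`, where δ is suppressed to 2 %
of its value (degraded, not perfectly null, structure). Gaussian low-pass
filtering of white noise was chosen over e.g. Voronoi domains because the
correlation length is directly controllable and the field statistics are
stationary.

Cohorts add seeded between-sample jitter — per-sample mean phase
(sd 0.20 rad), isotropic fraction (rel. sd 0.50), patch size (rel. sd
0.35) and phase spread (rel. sd 0.25) — emulating biological replicate
variability. Class presets encode the two opposite pathology scenarios at
n = 36 per class, 256×256 px: adenoma-like (δ̄ = 1.20, 12 % isotropic area
in 10 px foci) vs. carcinoma-like (δ̄ = 1.08, 16 % in 40 px foci), and
myoma-like vs. endometriosis-like with the reverse (birefringence-gain,
small-scale) contrast. These values were fixed once so that the cohorts
reproduce the qualitative phenomenology the pipeline is built for — the
carcinoma-like class shows fewer C and more L characteristic values, and
mean accuracy orders raw < counts < wavelet — with substantial class
overlap, as in real cohorts.

What passing phantom tests does **not** show: phantoms are pure retarder
fields with Gaussian statistics; real sections depolarize, diattenuate,
vary in thickness, and their δ distributions are unknown. Absolute
accuracy values on phantoms therefore say nothing about clinical accuracy;
only the *relative* behavior of the feature families and the scale
selectivity of the wavelet stage transfer.

## Problem sizes and numerical choices

Defaults were picked for desk-scale work: 256×256 images (a camera-scale
1280×960 frame changes nothing structurally), n = 36 per class, 10 cohort
seeds for trend/ordering properties, 2 seeds × 128×128 for null
calibration, 500 simulations for the rank-test level check. A full
two-class default cohort runs in ~10 s on one core. Determinism:
every stochastic step derives its seed from a `SeedSequence` of the master
seed (all seeds < 2³¹); reports embed a config hash and rerunning a config
reproduces feature tables bit-for-bit.

## Known limitations

* The pure-retarder model cannot represent depolarization; applying the
  pipeline to strongly scattering (thick) sections violates its premises.
* ε-thresholded singularity detection counts *pixels*, not topological
  singular points; no sub-pixel localization or charge is computed.
* The optimal-scale rule assumes a unimodal dispersion-versus-scale curve;
  multi-scale pathology would require inspecting the full ΔZ trace (kept
  in `ScaleSelection.delta_Z_trace`).
* The midpoint threshold rule is deliberately simple; it underestimates
  attainable Ac compared with ROC-optimal thresholds, uniformly across
  feature families.
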