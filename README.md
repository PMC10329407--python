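# polsing

Mueller-matrix polarization-singular + wavelet-decomposition diagnostics for
linearly birefringent tissue layers.

## The problem

Thin histological sections of fibrillar tissue (prostate, uterine wall, ...)
behave optically as spatially varying **linear retarders**: oriented
birefringent fibrils impose a per-pixel phase shift
δ = 2πΔn·l/λ between orthogonal polarization components, with optical-axis
orientation ρ set by the local fibril direction. Classical Mueller-matrix
(MM) imaging polarimetry summarizes such maps by whole-image statistics, which
averages away exactly the thing pathology changes: *where* and *at what
spatial scale* birefringence is gained or lost. Necrotic (carcinoma-like)
degradation erases birefringence over large domains; fibrotic
(endometriosis-like) overgrowth adds birefringence in small domains.

`polsing` implements a processing chain that keeps that localized, scale-
resolved information:

1. **Forward model / reconstruction** (`polsing.mueller`). The retarder MM

   M(ρ, δ) = Rot(2ρ) · Retarder(δ) · Rot(−2ρ),

   with f44 = cos δ, f42 = −f24 = sin 2ρ sin δ, f34 = −f43 = cos 2ρ sin δ, etc.
   The module also simulates the standard Stokes-polarimetric measurement
   (4 polarized illuminations × 6 analyzer projections), reconstructs Stokes
   images and the MM from intensities, and computes the azimuthal invariants
   F22;33 = (f22+f33)−1 = cos δ and F42;43 = √(f42²+f43²) = |sin δ|.

2. **Polarization singularities** (`polsing.singularities`). Pixels where
   δ = kπ transmit linear polarization (L-points); δ = π/2 + kπ produces
   circular polarization (C-points). On the invariants these appear as
   *characteristic values* (f44 = ±1 ↔ L, f44 = 0 ↔ C, and the
   complementary pairings for |sin δ| invariants). Thresholded masks are
   counted along rows/columns into scan profiles N(L, x), N(C, x), N(·, y).

3. **Scale-selective wavelet analysis** (`polsing.wavelet`). The MHAT
   (Ricker) continuous wavelet transform
   Q(a, b) = |a|^(−1/2) Σ_x q(x) Ω((x−b)/a), Ω(t) = (1−t²)e^(−t²/2),
   of the count profiles, with a two-stage (macro step 10 / micro step 2)
   search for the optimal scale A\* that maximizes the dispersion of the
   scale line Q_A(b).

4. **Statistics and diagnostic power** (`polsing.stats`). Central moments
   Z1 (mean M), Z2 (dispersion D), Z3, Z4 of profiles and scale lines;
   Mann–Whitney significance; sensitivity Se = p/(p+g)·100 %, specificity
   Sp = c/(c+d)·100 % and balanced accuracy Ac = 0.5(Se+Sp) for two-group
   differentiation.

5. **Phantoms and pipeline** (`polsing.phantom`, `polsing.pipeline`,
   `polsing` CLI). A synthetic-tissue generator producing two-class cohorts
   with controlled domain scale, mean retardance and necrotic-patch
   structure, and an end-to-end orchestrator that scores three feature
   families per cohort: raw invariant-map moments, singular-count moments,
   and wavelet scale-line moments.

## Worked example

Two-class phantom cohort (adenoma-like vs. carcinoma-like, 12 samples per
class, 256×256 pixels), full pipeline:

```python
from polsing import PipelineConfig, run_pipeline

config = PipelineConfig(n_per_class=12, seed=1)
report = run_pipeline(config)

for key, sel in report.a_star.items():
    print(f"A*[{key}] = {sel.A_star:g} px")
for fam, ac in sorted(report.family_best_ac().items()):
    print(f"best Ac [{fam}] = {ac:.2f} %")
row = report.diagnostics.set_index("feature").loc["QL_y_D"]
print(f"QL_y_D: p = {row.p_value:.2e}, Se = {row.Se:.1f} %, "
      f"Sp = {row.Sp:.1f} %, Ac = {row.Ac:.2f} %")
```

prints

```
A*[L_x] = 26 px
A*[L_y] = 20 px
A*[C_x] = 38 px
A*[C_y] = 34 px
best Ac [counts] = 83.33 %
best Ac [raw] = 54.17 %
best Ac [wavelet] = 87.50 %
QL_y_D: p = 1.11e-03, Se = 75.0 %, Sp = 100.0 %, Ac = 87.50 %
```

Reading: raw whole-map moments barely separate the classes (Ac ≈ 54 %),
counting singular characteristic values helps (Ac ≈ 83 %), and the moments
of the wavelet coefficients at the selected scale A\* — here 20–38 px,
bracketing the injected 10 px vs. 40 px patch structure — separate best
(Ac ≈ 88 %). `QL_y_D` is the dispersion D of the scale line Q_A*(b) of the
N(L, y) profile; its Mann–Whitney p-value and operating characteristics are
shown. The same run is available from the shell:

```sh
polsing phantom --preset carcinoma-like --out ./phantom
polsing mm simulate --input phantom/anisotropy.tif --output mm.tif
polsing run --config cfg.yaml
polsing report --input out/report.json
```

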