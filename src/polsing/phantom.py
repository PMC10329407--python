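"""Synthetic two-class tissue phantoms for the polarimetric pipeline.

A phantom emulates the anisotropy maps of a thin histological section made
of domains of oriented birefringent fibrils: a smooth random orientation
field ``rho`` with a controllable correlation length (the domain scale), a
phase-shift field ``delta`` sharing the same domain structure, and optional
near-isotropic patches where the birefringent structure has degraded
(``delta`` forced toward 0).

Class presets mirror two opposite pathology scenarios:

* carcinoma-like: necrotic degradation of the birefringent network —
  lower mean ``delta`` and a large fraction of large-scale isotropic
  patches (fewer circular-polarization singular points, more linear ones);
* endometriosis-like: overgrowth of fibrillar networks — higher mean
  ``delta`` concentrated in small-scale domains (the reverse trend).

The generators are deterministic given their seed; cohorts add seeded
between-sample variability of the class parameters so phantom samples
overlap like biological replicates do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .mueller import AnisotropyMap

__all__ = [
    "PhantomParams",
    "CohortJitter",
    "CohortSample",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
    "adenoma_like",
    "carcinoma_like",
    "myoma_like",
    "endometriosis_like",
]

#: Residual retardance factor inside "isotropic" (necrotic) patches.
_PATCH_RESIDUAL = 0.02


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters of one phantom anisotropy map.

    Parameters
    ----------
    shape : (int, int)
        Image height and width in pixels.
    domain_scale : float
        Correlation length of the orientation/retardance domains, pixels
        (distance at which the field autocorrelation falls to 1/e).
    delta_mean, delta_sd : float
        Mean and spread of the phase shift ``delta`` (radians); the field is
        clipped to [0, pi] so the circular-singularity condition
        ``delta = pi/2`` is interior.
    isotropic_fraction : float
        Fraction of the area overwritten by near-isotropic patches.
    patch_scale : float
        Characteristic patch size, pixels.
    seed : int
        Generator seed (deterministic output).
    """

    shape: tuple[int, int] = (256, 256)
    domain_scale: float = 16.0
    delta_mean: float = 1.2
    delta_sd: float = 0.35
    isotropic_fraction: float = 0.08
    patch_scale: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 8 or w < 8:
            raise ValueError("shape must be at least 8x8")
        if self.domain_scale < 1:
            raise ValueError("domain_scale must be >= 1 pixel")
        if not (0.0 <= self.isotropic_fraction <= 1.0):
            raise ValueError("isotropic_fraction must be in [0, 1]")
        if self.patch_scale < 1:
            raise ValueError("patch_scale must be >= 1 pixel")
        if not (0.0 <= self.delta_mean <= np.pi):
            raise ValueError("delta_mean must be in [0, pi]")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be non-negative")


def _smooth_unit_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with 1/e autocorrelation
    length ~ ``corr_length`` (Gaussian-filtered white noise, periodic BC)."""
    white = rng.standard_normal(shape)
    # filtered white noise has autocorrelation exp(-r^2 / (4 sigma^2));
    # the 1/e length is 2 sigma.
    sigma = max(corr_length / 2.0, 0.5)
    f = gaussian_filter(white, sigma=sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(params: PhantomParams) -> AnisotropyMap:
    """Generate one anisotropy map from :class:`PhantomParams`.

    The orientation field is the half-angle of a smooth random director
    (``rho = 0.5*atan2(g2, g1) mod pi``), the phase-shift field is a clipped
    Gaussian sharing the domain correlation structure, and a
    ``isotropic_fraction`` quantile of a patch-scale smooth field selects the
    near-isotropic patches.
    """
    rng = np.random.default_rng(params.seed)
    g1 = _smooth_unit_field(rng, params.shape, params.domain_scale)
    g2 = _smooth_unit_field(rng, params.shape, params.domain_scale)
    rho = np.mod(0.5 * np.arctan2(g2, g1), np.pi)

    z = _smooth_unit_field(rng, params.shape, params.domain_scale)
    delta = np.clip(params.delta_mean + params.delta_sd * z, 0.0, np.pi)

    if params.isotropic_fraction > 0:
        p = _smooth_unit_field(rng, params.shape, params.patch_scale)
        thr = np.quantile(p, 1.0 - params.isotropic_fraction)
        delta = np.where(p >= thr, delta * _PATCH_RESIDUAL, delta)

    return AnisotropyMap(rho=rho, delta=delta)


@dataclass(frozen=True)
class CohortJitter:
    """Between-sample variability applied when generating a cohort.

    Biological replicates of one tissue class differ in overall
    birefringence level, in how much of the section is degraded and in how
    large the degraded foci are.  ``delta_mean_sd`` jitters each sample's
    mean phase shift (radians); ``fraction_rel_sd`` and
    ``patch_scale_rel_sd`` jitter the isotropic fraction and patch size
    multiplicatively; ``delta_sd_rel_sd`` jitters the phase-shift spread.
    """

    delta_mean_sd: float = 0.20
    fraction_rel_sd: float = 0.50
    patch_scale_rel_sd: float = 0.35
    delta_sd_rel_sd: float = 0.25


@dataclass(frozen=True)
class CohortSample:
    label: str
    params: PhantomParams
    amap: AnisotropyMap


@dataclass(frozen=True)
class Cohort:
    """Labeled two-class collection of phantom samples."""

    samples: tuple[CohortSample, ...]
    seed: int

    def values(self, label: str) -> list[AnisotropyMap]:
        return [s.amap for s in self.samples if s.label == label]

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            if s.label not in seen:
                seen.append(s.label)
        return tuple(seen)


def _jittered(
    params: PhantomParams, jitter: CohortJitter, rng: np.random.Generator, seed: int
) -> PhantomParams:
    dm = float(np.clip(
        rng.normal(params.delta_mean, jitter.delta_mean_sd), 0.05, np.pi - 0.05
    ))
    frac = float(np.clip(
        params.isotropic_fraction * (1.0 + rng.normal(0.0, jitter.fraction_rel_sd)),
        0.0, 0.9,
    ))
    ps = float(np.clip(
        params.patch_scale * (1.0 + rng.normal(0.0, jitter.patch_scale_rel_sd)),
        2.0, None,
    ))
    dsd = float(np.clip(
        params.delta_sd * (1.0 + rng.normal(0.0, jitter.delta_sd_rel_sd)),
        0.0, None,
    ))
    return replace(params, delta_mean=dm, isotropic_fraction=frac,
                   patch_scale=ps, delta_sd=dsd, seed=seed)


def generate_cohort(
    classA_params: PhantomParams,
    classB_params: PhantomParams,
    n_per_class: int = 36,
    seed: int = 0,
    jitter: Optional[CohortJitter] = CohortJitter(),
    labels: tuple[str, str] = ("A", "B"),
) -> Cohort:
    """Generate a labeled two-class cohort of independent seeded phantoms.

    Each sample gets its own child seed from a :class:`numpy.random.SeedSequence`
    spawned off ``seed`` (bit-for-bit reproducible); ``jitter`` (set to None
    to disable) adds between-sample parameter variability.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_per_class + 1, dtype=np.uint32) & 0x7FFFFFFF
    jrng = np.random.default_rng(int(child[-1]))
    samples: list[CohortSample] = []
    for j, (label, base) in enumerate(zip(labels, (classA_params, classB_params))):
        for i in range(n_per_class):
            s = int(child[j * n_per_class + i])
            p = _jittered(base, jitter, jrng, s) if jitter is not None else replace(base, seed=s)
            samples.append(CohortSample(label=label, params=p, amap=generate_phantom(p)))
    return Cohort(samples=tuple(samples), seed=seed)


# ---------------------------------------------------------------------------
# Class presets: trend-calibrated study conditions (see docs/methods.md).

def adenoma_like(shape=(256, 256)) -> PhantomParams:
    """Benign prostate baseline: moderate birefringence, small degraded foci."""
    return PhantomParams(shape=shape, domain_scale=16.0, delta_mean=1.20,
                         delta_sd=0.35, isotropic_fraction=0.12, patch_scale=10.0)


def carcinoma_like(shape=(256, 256)) -> PhantomParams:
    """Malignant prostate: birefringence loss in large-scale necrotic patches."""
    return PhantomParams(shape=shape, domain_scale=16.0, delta_mean=1.08,
                         delta_sd=0.35, isotropic_fraction=0.16, patch_scale=40.0)


def myoma_like(shape=(256, 256)) -> PhantomParams:
    """Benign uterine baseline."""
    return PhantomParams(shape=shape, domain_scale=16.0, delta_mean=1.12,
                         delta_sd=0.30, isotropic_fraction=0.14, patch_scale=20.0)


def endometriosis_like(shape=(256, 256)) -> PhantomParams:
    """Endometriosis: birefringence gain in small-scale fibrillar domains."""
    return PhantomParams(shape=shape, domain_scale=10.0, delta_mean=1.30,
                         delta_sd=0.30, isotropic_fraction=0.08, patch_scale=8.0)
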