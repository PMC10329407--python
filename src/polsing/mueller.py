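"""Forward model and simulated Stokes polarimetry of linearly birefringent layers.

A thin fibrillar tissue layer is modelled as a spatially varying linear
retarder: at every pixel the optical axis makes an angle ``rho`` with the
horizontal and the two orthogonal linear components acquire a relative phase
shift ``delta = 2*pi*dn*l/lambda``.  Its Mueller matrix is the rotated
retarder

    M(rho, delta) = Rot(2*rho) . Retarder(delta) . Rot(-2*rho)

whose non-trivial elements are

    f22 = cos^2(2 rho) + sin^2(2 rho) cos(delta)
    f23 = f32 = cos(2 rho) sin(2 rho) (1 - cos(delta))
    f33 = sin^2(2 rho) + cos^2(2 rho) cos(delta)
    f42 = -f24 = sin(2 rho) sin(delta)
    f34 = -f43 = cos(2 rho) sin(delta)
    f44 = cos(delta)

with f11 = 1 and the remaining first-row/column elements zero (no
diattenuation, no depolarization).  The module also simulates the standard
Stokes-polarimetric measurement (four polarized illuminations, six analyzer
projections), reconstructs Stokes images and the Mueller matrix from
intensities, and computes the azimuthally invariant functionals

    F22;33 = (f22 + f33) - 1 = cos(delta)
    F42;43 = sqrt(f42^2 + f43^2) = |sin(delta)|
    F24;34 = sqrt(f24^2 + f34^2) = |sin(delta)|

used downstream for polarization-singularity detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OpticalParams",
    "AnisotropyMap",
    "MuellerImage",
    "IntensityStack",
    "StokesImageSet",
    "InvariantMaps",
    "ILLUMINATIONS",
    "ANALYZERS",
    "phase_from_optics",
    "mm_from_anisotropy",
    "simulate_intensities",
    "stokes_from_intensities",
    "mm_from_stokes",
    "compute_invariants",
]

#: Probe polarization states (illumination order used throughout):
#: linear 0 deg, 45 deg, 90 deg and right-circular.
ILLUMINATIONS = ("0", "45", "90", "circ")

_PROBE_STOKES = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],   # linear 0 deg
        [1.0, 0.0, 1.0, 0.0],   # linear 45 deg
        [1.0, -1.0, 0.0, 0.0],  # linear 90 deg
        [1.0, 0.0, 0.0, 1.0],   # right circular
    ]
)

#: Analyzer states (analyzer order used throughout).
ANALYZERS = ("0", "45", "90", "135", "R", "L")

_ANALYZER_STOKES = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [1.0, 0.0, -1.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0, -1.0],
    ]
)


@dataclass(frozen=True)
class OpticalParams:
    """Optical parameters of a birefringent layer.

    Parameters
    ----------
    wavelength : float
        Probe wavelength ``lambda`` in meters.
    birefringence : float
        Refractive-index difference ``dn`` (dimensionless, >= 0).
    thickness : float
        Geometric layer thickness ``l`` in meters.
    attenuation : float, optional
        Extinction coefficient ``tau`` in 1/cm.  Stored as metadata only;
        it does not enter the retarder model.
    """

    wavelength: float
    birefringence: float
    thickness: float
    attenuation: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if not (self.thickness > 0):
            raise ValueError("thickness must be positive")
        if self.birefringence < 0:
            raise ValueError("birefringence must be non-negative")


def phase_from_optics(params: OpticalParams) -> float:
    """Phase shift ``delta = 2*pi*dn*l/lambda`` in radians (not wrapped)."""
    return 2.0 * np.pi * params.birefringence * params.thickness / params.wavelength


@dataclass
class AnisotropyMap:
    """Per-pixel optical-axis orientation ``rho`` and phase shift ``delta``.

    ``rho`` is wrapped into [0, pi) on construction (the retarder model is
    pi-periodic in the axis orientation).  Both arrays share shape (H, W).
    """

    rho: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.rho.shape != self.delta.shape:
            raise ValueError(
                f"rho and delta shapes differ: {self.rho.shape} vs {self.delta.shape}"
            )
        if self.rho.ndim != 2:
            raise ValueError("rho/delta must be 2-D (H, W) arrays")
        if not (np.all(np.isfinite(self.rho)) and np.all(np.isfinite(self.delta))):
            raise ValueError("rho and delta must be finite")
        self.rho = np.mod(self.rho, np.pi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rho.shape


@dataclass
class MuellerImage:
    """Per-pixel 4x4 real Mueller matrix, f11-normalized; shape (H, W, 4, 4).

    ``invalid`` optionally marks pixels where reconstruction failed
    (f11 ~ 0, no transmitted intensity).
    """

    elements: np.ndarray
    invalid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[2:] != (4, 4):
            raise ValueError("elements must have shape (H, W, 4, 4)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements.shape[:2]

    def element(self, i: int, k: int) -> np.ndarray:
        """Map of element f_ik with 1-based indices i, k in {1..4}."""
        if not (1 <= i <= 4 and 1 <= k <= 4):
            raise ValueError("element indices are 1-based in {1..4}")
        return self.elements[:, :, i - 1, k - 1]

    def normalized(self) -> "MuellerImage":
        """Return a copy with every pixel matrix divided by its f11."""
        f11 = self.elements[:, :, 0, 0]
        bad = ~(np.abs(f11) > 1e-12)
        safe = np.where(bad, 1.0, f11)
        out = self.elements / safe[:, :, None, None]
        invalid = bad if bad.any() else self.invalid
        return MuellerImage(out, invalid=invalid)


@dataclass
class IntensityStack:
    """Analyzer intensities, shape (H, W, 4 illuminations, 6 analyzers).

    Axis order follows :data:`ILLUMINATIONS` and :data:`ANALYZERS`.
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4 or self.intensities.shape[2:] != (4, 6):
            raise ValueError("intensities must have shape (H, W, 4, 6)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]


@dataclass
class StokesImageSet:
    """Output Stokes vectors per illumination, shape (H, W, 4 illum, 4 Stokes)."""

    stokes: np.ndarray

    def __post_init__(self) -> None:
        self.stokes = np.asarray(self.stokes, dtype=float)
        if self.stokes.ndim != 4 or self.stokes.shape[2:] != (4, 4):
            raise ValueError("stokes must have shape (H, W, 4, 4)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stokes.shape[:2]


@dataclass
class InvariantMaps:
    """Azimuthally invariant Mueller functionals, each of shape (H, W)."""

    f44: np.ndarray
    F2233: np.ndarray
    F4243: np.ndarray
    F2434: np.ndarray

    _NAMES = ("f44", "F2233", "F4243", "F2434")

    def get(self, name: str) -> np.ndarray:
        """Fetch a map by invariant name (``f44``, ``F2233``, ``F4243``, ``F2434``)."""
        key = name.replace(";", "").replace(",", "")
        if key not in self._NAMES:
            raise KeyError(f"unknown invariant {name!r}; expected one of {self._NAMES}")
        return getattr(self, key)

    @property
    def shape(self) -> tuple[int, int]:
        return self.f44.shape


def mm_from_anisotropy(amap: AnisotropyMap) -> MuellerImage:
    """Mueller image of a linearly birefringent layer from (rho, delta) maps."""
    two_rho = 2.0 * amap.rho
    c = np.cos(two_rho)
    s = np.sin(two_rho)
    cd = np.cos(amap.delta)
    sd = np.sin(amap.delta)

    h, w = amap.shape
    m = np.zeros((h, w, 4, 4), dtype=float)
    m[:, :, 0, 0] = 1.0
    m[:, :, 1, 1] = c * c + s * s * cd
    m[:, :, 1, 2] = c * s * (1.0 - cd)
    m[:, :, 2, 1] = m[:, :, 1, 2]
    m[:, :, 2, 2] = s * s + c * c * cd
    m[:, :, 3, 1] = s * sd           # f42
    m[:, :, 1, 3] = -m[:, :, 3, 1]   # f24 = -f42
    m[:, :, 2, 3] = c * sd           # f34
    m[:, :, 3, 2] = -m[:, :, 2, 3]   # f43 = -f34
    m[:, :, 3, 3] = cd
    return MuellerImage(m)


def simulate_intensities(
    mm: MuellerImage, noise_sd: float = 0.0, seed: Optional[int] = None
) -> IntensityStack:
    """Simulate the six-analyzer, four-illumination intensity measurement.

    Each unit-intensity probe Stokes vector ``S_p`` is propagated through the
    per-pixel Mueller matrix, and each analyzer records the ideal-polarizer
    projection ``I = 0.5 * (S'_1 + a2 S'_2 + a3 S'_3 + a4 S'_4)``.  Optional
    additive Gaussian noise of standard deviation ``noise_sd`` (in units of
    the unit probe intensity) is applied and clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    # S'[h,w,p,i] = sum_k M[h,w,i,k] * S_p[k]
    s_out = np.einsum("hwik,pk->hwpi", mm.elements, _PROBE_STOKES)
    inten = 0.5 * np.einsum("hwpi,qi->hwpq", s_out, _ANALYZER_STOKES)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0.0, noise_sd, size=inten.shape)
    return IntensityStack(np.clip(inten, 0.0, None))


def stokes_from_intensities(stack: IntensityStack) -> StokesImageSet:
    """Stokes images from analyzer intensities.

    Per illumination: ``SV1 = I0 + I90``, ``SV2 = I0 - I90``,
    ``SV3 = I45 - I135``, ``SV4 = I_R - I_L``.
    """
    i = stack.intensities
    i0, i45, i90, i135, ir, il = (i[:, :, :, q] for q in range(6))
    sv = np.stack([i0 + i90, i0 - i90, i45 - i135, ir - il], axis=-1)
    return StokesImageSet(sv)


def mm_from_stokes(stokes: StokesImageSet) -> MuellerImage:
    """Mueller image from the Stokes images of the four probe illuminations.

    The sixteen elements follow from linearity of the Mueller transfer:
    ``f_i1 = 0.5 (SV_i^0 + SV_i^90)``, ``f_i2 = 0.5 (SV_i^0 - SV_i^90)``,
    ``f_i3 = SV_i^45 - f_i1``, ``f_i4 = SV_i^circ - f_i1``.  The result is
    normalized so f11 = 1; pixels with f11 ~ 0 are flagged invalid.
    """
    sv = stokes.stokes  # (H, W, illum, i)
    sv0 = sv[:, :, 0, :]
    sv45 = sv[:, :, 1, :]
    sv90 = sv[:, :, 2, :]
    svc = sv[:, :, 3, :]

    h, w = stokes.shape
    m = np.empty((h, w, 4, 4), dtype=float)
    m[:, :, :, 0] = 0.5 * (sv0 + sv90)
    m[:, :, :, 1] = 0.5 * (sv0 - sv90)
    m[:, :, :, 2] = sv45 - m[:, :, :, 0]
    m[:, :, :, 3] = svc - m[:, :, :, 0]
    return MuellerImage(m).normalized()


def compute_invariants(mm: MuellerImage) -> InvariantMaps:
    """Azimuthal invariants f44, F22;33, F42;43 and F24;34 of a Mueller image.

    For the pure retarder model the four maps obey f44 = F22;33 = cos(delta)
    and F42;43 = F24;34 = |sin(delta)|.
    """
    e = mm.elements
    f44 = e[:, :, 3, 3].copy()
    f2233 = e[:, :, 1, 1] + e[:, :, 2, 2] - 1.0
    f4243 = np.hypot(e[:, :, 3, 1], e[:, :, 3, 2])
    f2434 = np.hypot(e[:, :, 1, 3], e[:, :, 2, 3])
    return InvariantMaps(f44=f44, F2233=f2233, F4243=f4243, F2434=f2434)
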