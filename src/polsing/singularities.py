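"""Detection of polarization-singular characteristic values and scan counts.

In a linearly birefringent layer probed with polarized light, pixels where the
phase shift satisfies delta = k*pi transmit linearly polarized light for any
probe azimuth (L-points: handedness undefined), while delta = pi/2 + k*pi
produces circular polarization (C-points: azimuth undefined).  On the
azimuthally invariant Mueller functionals these singular states appear as
*characteristic values*:

    f44, F22;33 = +/-1  <->  L-point        f44, F22;33 = 0     <->  C-point
    F42;43, F24;34 = 0  <->  L-point        F42;43, F24;34 = +/-1 <-> C-point

Characteristic pixels are thresholded with a tolerance ``epsilon`` and then
counted along image rows/columns to produce 1-D scan-count profiles
N(L, x), N(C, x) (and the orthogonal N(., y)) that feed the wavelet stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mueller import InvariantMaps

__all__ = [
    "CharacteristicMask",
    "CountProfile",
    "detect_characteristic_points",
    "scan_counts",
]

#: Default detection tolerance in invariant units (~1% of the [-1, 1] range).
DEFAULT_EPSILON = 0.02

# target value (0 or +/-1) per (invariant, kind)
_TARGETS = {
    ("f44", "L"): "one",
    ("f44", "C"): "zero",
    ("F2233", "L"): "one",
    ("F2233", "C"): "zero",
    ("F4243", "L"): "zero",
    ("F4243", "C"): "one",
    ("F2434", "L"): "zero",
    ("F2434", "C"): "one",
}


@dataclass
class CharacteristicMask:
    """Boolean map of pixels at a characteristic value."""

    mask: np.ndarray
    kind: str
    source_invariant: str
    tolerance: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def total(self) -> int:
        return int(self.mask.sum())


@dataclass
class CountProfile:
    """1-D profile of characteristic-pixel counts along one scan axis.

    ``axis='x'`` counts per image column (length W, the Ox scan);
    ``axis='y'`` counts per image row (length H, the Oy scan).
    """

    counts: np.ndarray
    axis: str
    kind: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")

    def __len__(self) -> int:
        return self.counts.size


def detect_characteristic_points(
    inv: InvariantMaps,
    source_invariant: str = "f44",
    kind: str = "L",
    epsilon: float = DEFAULT_EPSILON,
) -> CharacteristicMask:
    """Mask pixels whose invariant sits at the singular characteristic value.

    A pixel is included iff ``|value - target| <= epsilon``, where the target
    is 0 or +/-1 (either sign counts) according to the (invariant, kind)
    pairing above.

    Parameters
    ----------
    inv : InvariantMaps
    source_invariant : {'f44', 'F2233', 'F4243', 'F2434'}
    kind : {'L', 'C'}
    epsilon : float
        Non-negative tolerance in invariant units.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    kind = kind.upper()
    key = source_invariant.replace(";", "").replace(",", "")
    try:
        target = _TARGETS[(key, kind)]
    except KeyError:
        raise ValueError(
            f"unknown (invariant, kind) pairing: ({source_invariant!r}, {kind!r})"
        ) from None
    values = inv.get(key)
    if target == "zero":
        mask = np.abs(values) <= epsilon
    else:  # +/-1, either sign
        mask = np.abs(np.abs(values) - 1.0) <= epsilon
    return CharacteristicMask(mask=mask, kind=kind, source_invariant=key, tolerance=epsilon)


def scan_counts(
    mask: CharacteristicMask, axis: str = "x", cumulative: bool = False
) -> CountProfile:
    """Count characteristic pixels along one scan direction.

    ``axis='x'`` returns, for every column j, the number of masked pixels in
    that column (scanning each pixel row along Ox and totalling per column);
    ``axis='y'`` counts per row.  With ``cumulative=True`` the running total
    along the profile is returned instead of per-line counts (an alternative
    reading of "the number within the corresponding column", off by default).
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    counts = mask.mask.sum(axis=0 if axis == "x" else 1).astype(np.int64)
    if cumulative:
        counts = np.cumsum(counts)
    return CountProfile(counts=counts, axis=axis, kind=mask.kind)
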