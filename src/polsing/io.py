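"""File formats: multi-plane TIFF stacks, CSV profiles/fields, JSON sidecars.

Conventions
-----------
* Mueller image: 16-plane 32-bit float TIFF, plane order f11, f12, ..., f44
  (row-major); renormalized to f11 = 1 on load.
* Intensity stack: 24-plane float TIFF, illumination-major / analyzer-minor,
  with the ordering recorded in a ``.json`` sidecar.
* Anisotropy map: 2-plane float TIFF (rho, delta).
* Characteristic mask: 8-bit TIFF (0/255).
* Count profile: 2-column CSV (index, count); wavelet field: CSV matrix
  (rows = scales, columns = positions).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .mueller import (
    ANALYZERS,
    ILLUMINATIONS,
    AnisotropyMap,
    IntensityStack,
    MuellerImage,
)
from .singularities import CharacteristicMask, CountProfile
from .wavelet import ScaleSelection, WaveletField

PathLike = Union[str, Path]


def save_mueller_tiff(path: PathLike, mm: MuellerImage) -> None:
    h, w = mm.shape
    planes = mm.elements.reshape(h, w, 16).transpose(2, 0, 1).astype(np.float32)
    tifffile.imwrite(str(path), planes, photometric="minisblack")


def load_mueller_tiff(path: PathLike) -> MuellerImage:
    planes = tifffile.imread(str(path)).astype(float)
    if planes.ndim != 3 or planes.shape[0] != 16:
        raise ValueError("expected a 16-plane Mueller TIFF stack")
    elements = planes.transpose(1, 2, 0).reshape(planes.shape[1], planes.shape[2], 4, 4)
    return MuellerImage(elements).normalized()


def save_intensity_tiff(path: PathLike, stack: IntensityStack) -> None:
    path = Path(path)
    h, w = stack.shape
    planes = stack.intensities.reshape(h, w, 24).transpose(2, 0, 1).astype(np.float32)
    tifffile.imwrite(str(path), planes, photometric="minisblack")
    sidecar = {
        "plane_order": "illumination-major, analyzer-minor",
        "illuminations": list(ILLUMINATIONS),
        "analyzers": list(ANALYZERS),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_intensity_tiff(path: PathLike) -> IntensityStack:
    planes = tifffile.imread(str(path)).astype(float)
    if planes.ndim != 3 or planes.shape[0] != 24:
        raise ValueError("expected a 24-plane intensity TIFF stack")
    arr = planes.transpose(1, 2, 0).reshape(planes.shape[1], planes.shape[2], 4, 6)
    return IntensityStack(arr)


def save_anisotropy_tiff(path: PathLike, amap: AnisotropyMap) -> None:
    planes = np.stack([amap.rho, amap.delta]).astype(np.float32)
    tifffile.imwrite(str(path), planes, photometric="minisblack")


def load_anisotropy_tiff(path: PathLike) -> AnisotropyMap:
    planes = tifffile.imread(str(path)).astype(float)
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise ValueError("expected a 2-plane (rho, delta) TIFF stack")
    return AnisotropyMap(rho=planes[0], delta=planes[1])


def save_mask_tiff(path: PathLike, mask: CharacteristicMask) -> None:
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255), photometric="minisblack")


def save_invariants_tiff(path: PathLike, inv) -> None:
    planes = np.stack([inv.f44, inv.F2233, inv.F4243, inv.F2434]).astype(np.float32)
    tifffile.imwrite(str(path), planes, photometric="minisblack")


def profile_to_csv(path: PathLike, profile: CountProfile) -> None:
    pd.DataFrame(
        {"index": np.arange(len(profile)), "count": profile.counts}
    ).to_csv(path, index=False)


def profile_from_csv(path: PathLike, axis: str = "x", kind: str = "L") -> CountProfile:
    df = pd.read_csv(path)
    return CountProfile(counts=df["count"].to_numpy(), axis=axis, kind=kind)


def wavelet_field_to_csv(path: PathLike, field: WaveletField) -> None:
    pd.DataFrame(field.Q, index=field.scales, columns=field.positions).to_csv(
        path, index_label="scale"
    )


def save_wavelet_heatmap(path: PathLike, field: WaveletField) -> None:
    """Render |Q(a,b)| as a heat map image (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.pcolormesh(field.positions, field.scales, field.Q, shading="nearest",
                       cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="Q(a, b)")
    ax.set_xlabel("position b (pixel)")
    ax.set_ylabel("scale a (pixel)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def scale_selection_to_json(path: PathLike, sel: ScaleSelection) -> None:
    Path(path).write_text(json.dumps(
        {
            "A_star": sel.A_star,
            "macro_interval": list(sel.macro_interval),
            "fallback": sel.fallback,
            "delta_Z_trace": [list(t) for t in sel.delta_Z_trace],
        },
        indent=1,
    ))
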