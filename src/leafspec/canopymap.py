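"""Per-pixel canopy pigment mapping and per-type summary statistics.

A predictor trained on leaf spectra is applied to every foreground pixel of
a calibrated canopy cube: each pixel spectrum is preprocessed exactly as the
training data was, reduced to the training band selection, and scored.
Background pixels carry a sentinel (NaN by default, rendered black).  There
is no spatial smoothing — the map is a raw pixelwise inversion, preserving
vein-scale texture.

Out-of-range predictions (e.g. negative mg/g) are kept and flagged in the
sidecar rather than clipped, so distribution statistics over the canopy
stay honest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hsicube import HyperCube, Mask
from .prep import PrepSpec, apply_prep

__all__ = ["PigmentMap", "invert_canopy", "summarize_by_type", "render_map"]

PLANES = ("chla", "chlb", "car", "tpc")


@dataclass
class PigmentMap:
    """Four H x W pigment planes (mg/g) sharing one foreground mask."""

    planes: dict  # name -> H x W float array, sentinel outside mask
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)
    sentinel: float = np.nan

    def plane(self, name: str) -> np.ndarray:
        return self.planes[name]

    def foreground_values(self, name: str) -> np.ndarray:
        return self.planes[name][self.mask]


def invert_canopy(
    cube: HyperCube,
    mask: Mask | np.ndarray,
    predictors: dict,
    prep: PrepSpec = PrepSpec(),
    selection=None,
    sentinel: float = np.nan,
    tile_rows: int = 64,
) -> PigmentMap:
    """Score every foreground pixel of a calibrated cube.

    ``predictors`` maps plane names (any subset of chla/chlb/car/tpc) to
    fitted predictors exposing ``predict(X) -> yhat``; a ``tpc`` plane is
    synthesized as the sum of the three pigments when absent and all three
    are present.  ``selection`` (a SelectionResult or an index array)
    restricts pixels to the training bands after preprocessing.  Pixels are
    streamed in row tiles so full-frame cubes fit modest memory.
    """
    if cube.kind != "reflectance":
        raise ValueError("invert_canopy expects a calibrated cube")
    fg = mask.foreground if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if fg.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    sel_idx = None
    if selection is not None:
        sel_idx = np.asarray(getattr(selection, "selected", selection))

    H, W, B = cube.shape
    planes = {name: np.full((H, W), sentinel) for name in predictors}
    for r0 in range(0, H, tile_rows):
        r1 = min(r0 + tile_rows, H)
        tile_mask = fg[r0:r1]
        if not tile_mask.any():
            continue
        px = cube.data[r0:r1][tile_mask]  # n_pix x B
        px = apply_prep(prep, px, cube.wavelengths)
        if sel_idx is not None:
            px = px[:, sel_idx]
        for name, pred in predictors.items():
            vals = np.asarray(pred.predict(px), dtype=float).ravel()
            planes[name][r0:r1][tile_mask] = vals
    if "tpc" not in planes and all(p in planes for p in ("chla", "chlb", "car")):
        tpc = np.full((H, W), sentinel)
        tpc[fg] = planes["chla"][fg] + planes["chlb"][fg] + planes["car"][fg]
        planes["tpc"] = tpc
    n_negative = int(
        sum(np.sum(planes[p][fg] < 0) for p in planes if fg.any())
    )
    return PigmentMap(
        planes=planes,
        mask=fg,
        provenance={
            "prep": prep.method,
            "n_foreground": int(fg.sum()),
            "n_negative_predictions": n_negative,
            "bands_used": None if sel_idx is None else sel_idx.tolist(),
        },
        sentinel=sentinel,
    )


def summarize_by_type(maps: list, labels: list) -> pd.DataFrame:
    """Pixel-pooled distribution statistics per type and pigment.

    Pools the foreground pixels of every map sharing a label and reports
    mean, sd, quartiles and the coefficient of variation (sd/mean) per
    pigment plane.  Duplicating a map changes pixel counts but not the
    statistics of its type.
    """
    if len(maps) != len(labels):
        raise ValueError("each map needs a type label")
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValueError("unlabeled map")
    rows = []
    for typ in sorted(set(labels)):
        group = [m for m, l in zip(maps, labels) if l == typ]
        plane_names = group[0].planes.keys()
        for name in plane_names:
            vals = np.concatenate([m.foreground_values(name) for m in group])
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=0))
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "type": typ,
                    "pigment": name,
                    "n_pixels": int(vals.size),
                    "mean": mean,
                    "sd": sd,
                    "q25": float(q25),
                    "median": float(q50),
                    "q75": float(q75),
                    "cv": sd / mean if mean != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def render_map(
    pmap: PigmentMap,
    plane: str,
    out,
    colormap: str = "viridis",
) -> dict:
    """Write an 8-bit false-color PNG of one plane, background black.

    Foreground values are min-max scaled into the colormap; the value
    range, colormap name and negative-prediction count go to a JSON
    sidecar.  Returns the sidecar dict.
    """
    from matplotlib import colormaps
    from PIL import Image

    if plane not in pmap.planes:
        raise ValueError(f"unknown plane {plane!r}")
    values = pmap.planes[plane]
    fg = pmap.mask & np.isfinite(values)
    if not fg.any():
        raise ValueError("all-sentinel plane: nothing to render")
    vmin, vmax = float(values[fg].min()), float(values[fg].max())
    span = vmax - vmin if vmax > vmin else 1.0
    norm = np.zeros_like(values, dtype=float)
    norm[fg] = (values[fg] - vmin) / span
    cmap = colormaps[colormap]
    rgba = (cmap(norm) * 255).astype(np.uint8)
    rgba[~fg] = (0, 0, 0, 255)  # background black
    out = Path(out)
    Image.fromarray(rgba[:, :, :3]).save(out.with_suffix(".png"))
    sidecar = {
        "plane": plane,
        "vmin": vmin,
        "vmax": vmax,
        "colormap": colormap,
        "n_negative": int(np.sum(values[fg] < 0)),
    }
    out.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
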