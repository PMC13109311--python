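"""Hyperspectral cube I/O, reflectance calibration, and spectral extraction.

A push-broom Vis-NIR imager records raw counts ``R_raw``; reflectance is
recovered with a white reference (a high-reflectivity flat plate) and a dark
reference (shutter closed) as ``R = (R_raw - R_d) / (R_w - R_d)`` per band.
The canopy is separated from the background by thresholding a single
near-infrared band (default 748.76 nm, on the NIR plateau where the
vegetation/background contrast is maximal), and per-leaf or per-canopy
spectra are the arithmetic mean over the selected pixels.

Cubes are exchanged as ENVI header + raw binary pairs (BSQ/BIL/BIP, float32
or uint16), the lingua franca of hyperspectral tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "HyperCube",
    "ReferencePair",
    "Mask",
    "ROISet",
    "calibrate_reflectance",
    "segment_canopy",
    "mean_spectrum",
    "read_envi",
    "write_envi",
]


@dataclass
class HyperCube:
    """H x W x B stack with a wavelength axis.

    ``kind`` distinguishes raw sensor counts from calibrated reflectance so
    downstream stages can refuse uncalibrated input.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "reflectance"  # "raw" | "reflectance"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength axis")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self):
        return self.data.shape

    def band_index(self, band_nm: float) -> int:
        """Index of the grid band nearest to ``band_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - band_nm)))


@dataclass
class ReferencePair:
    """White and dark reference measurements.

    Each reference may be a full cube (averaged over the spatial axes,
    push-broom style) or a per-band vector.
    """

    white: np.ndarray
    dark: np.ndarray

    def per_band(self) -> tuple[np.ndarray, np.ndarray]:
        def reduce(ref):
            a = np.asarray(ref, dtype=float)
            if a.ndim == 3:
                return a.mean(axis=(0, 1))
            if a.ndim == 1:
                return a
            raise ValueError("reference must be a cube or a per-band vector")

        return reduce(self.white), reduce(self.dark)


@dataclass
class Mask:
    """Boolean foreground map plus the provenance of its threshold."""

    foreground: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())


@dataclass
class ROISet:
    """Labeled pixel index sets, e.g. leaf-edge and leaf-center regions."""

    rois: dict  # label -> (rows, cols) index arrays

    def pixels(self, label: str):
        rows, cols = self.rois[label]
        if len(rows) == 0:
            raise ValueError(f"ROI {label!r} is empty")
        return np.asarray(rows), np.asarray(cols)


def calibrate_reflectance(raw: HyperCube, refs: ReferencePair) -> HyperCube:
    """Black/white reference calibration, per band:

        R = (R_raw - R_d) / (R_w - R_d)

    Bands where the white reference does not exceed the dark reference are
    a hard error (the denominator would be non-positive), reported by band
    index and wavelength.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw cube")
    white, dark = refs.per_band()
    if white.size != raw.shape[2] or dark.size != raw.shape[2]:
        raise ValueError("reference band count does not match cube")
    denom = white - dark
    bad = np.where(denom <= 0)[0]
    if bad.size:
        b = int(bad[0])
        raise ValueError(
            f"white <= dark at band {b} ({raw.wavelengths[b]:.2f} nm); "
            f"{bad.size} bad band(s) total"
        )
    refl = (raw.data.astype(float) - dark) / denom
    return HyperCube(data=refl, wavelengths=raw.wavelengths, kind="reflectance")


def segment_canopy(
    cube: HyperCube,
    band_nm: float = 748.76,
    threshold: float | None = None,
) -> Mask:
    """Threshold one NIR band into a foreground (canopy) mask.

    The band nearest ``band_nm`` is selected; Otsu's method picks the
    threshold unless a fixed ``threshold`` is given.  Foreground is the
    high-reflectance side.  A degenerate (empty or full) mask is returned
    with a warning rather than raised, so batch pipelines can continue.
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_canopy expects a calibrated cube")
    if not cube.wavelengths[0] <= band_nm <= cube.wavelengths[-1]:
        raise ValueError(f"band {band_nm} nm outside wavelength range")
    bi = cube.band_index(band_nm)
    plane = cube.data[:, :, bi].astype(float)
    if threshold is None:
        if np.ptp(plane) == 0:
            warnings.warn("uniform band image: degenerate threshold")
            thr = float(plane.flat[0])
        else:
            thr = float(threshold_otsu(plane))
        method = "otsu"
    else:
        thr = float(threshold)
        method = "fixed"
    fg = plane > thr
    if fg.sum() == 0 or fg.all():
        warnings.warn("degenerate segmentation: mask is empty or full")
    return Mask(
        foreground=fg,
        provenance={
            "band_index": bi,
            "band_nm": float(cube.wavelengths[bi]),
            "threshold": thr,
            "method": method,
        },
    )


def mean_spectrum(cube: HyperCube, pixels) -> np.ndarray:
    """Arithmetic mean spectrum over the selected pixels.

    ``pixels`` may be a :class:`Mask`, a boolean H x W array, or a
    ``(rows, cols)`` index pair (one ROI entry).
    """
    if isinstance(pixels, Mask):
        sel = pixels.foreground
    else:
        sel = pixels
    if isinstance(sel, np.ndarray) and sel.dtype == bool:
        if sel.shape != cube.shape[:2]:
            raise ValueError("mask shape does not match cube")
        if not sel.any():
            raise ValueError("empty pixel selection")
        return cube.data[sel].mean(axis=0)
    rows, cols = sel
    rows, cols = np.asarray(rows), np.asarray(cols)
    if rows.size == 0:
        raise ValueError("empty pixel selection")
    return cube.data[rows, cols, :].mean(axis=0)


# ---------------------------------------------------------------------------
# ENVI header + binary I/O
#
# Minimal dialect: interleaves bsq/bil/bip, data types 4 (float32) and
# 12 (uint16), byte order 0, wavelengths required.

_DTYPES = {4: np.float32, 12: np.uint16}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


def write_envi(cube: HyperCube, path, interleave: str = "bsq") -> None:
    """Write ``path``.hdr + ``path``.raw in the given interleave.

    float64 cubes are stored as float32 (dtype code 4); uint16 passes
    through as code 12.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = cube.data
    if data.dtype == np.uint16:
        out = data
    else:
        out = data.astype(np.float32)
    h, w, b = out.shape
    if interleave == "bip":
        arr = out  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(out, (0, 2, 1))  # (lines, bands, samples)
    else:
        arr = np.transpose(out, (2, 0, 1))  # (bands, lines, samples)
    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[out.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    arr.tofile(path.with_suffix(".raw"))


def _parse_envi_header(text: str) -> dict:
    # Collapse { ... } blocks (possibly multi-line) before splitting fields.
    text = text.replace("\r\n", "\n")
    fields = {}
    buf = None
    key = None
    for line in text.split("\n"):
        line = line.strip()
        if buf is not None:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                buf = None
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf = k, v
        else:
            fields[k] = v
    return fields


def read_envi(path) -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    Raises on missing wavelengths, band-count mismatch, or dialects outside
    the supported interleaves/data types, naming the offending field.
    """
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as e:
        raise ValueError(f"ENVI header missing field {e.args[0]!r}") from e
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength block")
    wl = np.array(
        [float(x) for x in fields["wavelength"].strip("{} ").split(",") if x.strip()]
    )
    if wl.size != b:
        raise ValueError(f"header bands={b} but wavelength list has {wl.size}")
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    raw = np.fromfile(path.with_suffix(".raw"), dtype=_DTYPES[dtype_code])
    if raw.size != h * w * b:
        raise ValueError("binary size does not match header dimensions")
    if interleave == "bip":
        data = raw.reshape(h, w, b)
    elif interleave == "bil":
        data = np.transpose(raw.reshape(h, b, w), (0, 2, 1))
    else:
        data = np.transpose(raw.reshape(b, h, w), (1, 2, 0))
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wl)


def write_mask(mask: Mask, path) -> None:
    """Save a mask as 0/255 PNG plus a JSON provenance sidecar."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray((mask.foreground.astype(np.uint8)) * 255)
    img.save(path.with_suffix(".png"))
    path.with_suffix(".json").write_text(json.dumps(mask.provenance, indent=2))
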