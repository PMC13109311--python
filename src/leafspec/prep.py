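"""Spectral preprocessing: moving average, SNV, first derivative.

All three transforms are fit-free (no statistics learned from a calibration
set) and preserve the band count, so wavelength indices keep their meaning
across the modeling grid and preprocessing can be applied before or after
sample splitting without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PrepSpec", "moving_average", "snv", "first_derivative", "apply_prep"]

_METHODS = ("none", "ma", "snv", "d1")


@dataclass(frozen=True)
class PrepSpec:
    """Preprocessing choice: method in {none, ma, snv, d1} + MA window."""

    method: str = "none"
    window: int = 5

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar mean across bands; the window shrinks at the edges.

    Edge bands average only the in-range part of the window — no padding
    values are invented.  Works on one spectrum or an n x B matrix (last
    axis is bands).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    x = np.asarray(x, dtype=float)
    B = x.shape[-1]
    if window > B:
        raise ValueError("window exceeds band count")
    if window == 1:
        return x.copy()  # exact identity, no cumsum round-off
    half = window // 2
    csum = np.cumsum(x, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    idx = np.arange(B)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, B - 1) + 1
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per spectrum, subtract mean, divide by sd.

    Uses the sample standard deviation (ddof=1), fixed project-wide.
    Zero-variance spectra are an explicit error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance spectrum: SNV undefined")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def first_derivative(x: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """dR/dlambda by central differences (one-sided at the ends).

    Exact for affine spectra; band count preserved.  Delegates to
    :func:`numpy.gradient`, which implements precisely this scheme on a
    non-uniform grid.
    """
    x = np.asarray(x, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if x.shape[-1] < 3:
        raise ValueError("first derivative needs >= 3 bands")
    return np.gradient(x, wl, axis=-1)


def apply_prep(spec: PrepSpec, x: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Dispatch one PrepSpec over a spectrum or spectra matrix."""
    if spec.method == "none":
        return np.asarray(x, dtype=float)
    if spec.method == "ma":
        return moving_average(x, spec.window)
    if spec.method == "snv":
        return snv(x)
    return first_derivative(x, wavelengths)
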