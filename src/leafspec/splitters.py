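"""Calibration/prediction set partitioning: Random, Kennard-Stone, SPXY.

Kennard-Stone (KS) seeds the calibration set with the globally farthest
sample pair, then greedily adds the sample whose minimum distance to the
chosen set is maximal (max-min), giving a deterministic, well-spread
calibration set.  SPXY applies the same greedy rule to a joint distance

    d(i, j) = d_x(i, j) / max(d_x) + d_y(i, j) / max(d_y)

with Euclidean distance in spectral space and |y_i - y_j| in the response,
so the calibration set also spans the target range (the canonical Galvao
formulation).  Ties in the max-min rule break toward the smallest index so
repeated runs are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "random_split", "kennard_stone", "spxy"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index lists covering every sample."""

    calib_idx: np.ndarray
    pred_idx: np.ndarray
    method: str
    ratio: float
    seed: int | None = None

    def __post_init__(self):
        ci, pi = np.asarray(self.calib_idx), np.asarray(self.pred_idx)
        n = ci.size + pi.size
        combined = np.sort(np.concatenate([ci, pi]))
        if not np.array_equal(combined, np.arange(n)):
            raise ValueError("calib/pred indices must partition 0..n-1")
        object.__setattr__(self, "calib_idx", ci)
        object.__setattr__(self, "pred_idx", pi)


def _calib_size(n: int, ratio: float) -> int:
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    k = int(round(ratio * n))
    if k < 1 or k >= n:
        raise ValueError("split leaves one side empty")
    return k


def random_split(n: int, ratio: float = 0.75, seed: int = 0) -> SplitResult:
    """Uniform draw without replacement into the calibration set."""
    k = _calib_size(n, ratio)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitResult(
        calib_idx=np.sort(perm[:k]),
        pred_idx=np.sort(perm[k:]),
        method="random",
        ratio=ratio,
        seed=seed,
    )


def _greedy_maxmin(D: np.ndarray, k: int) -> np.ndarray:
    """Max-min greedy selection on a full distance matrix.

    Starts from the farthest pair; ties break toward the smaller index
    (argmax returns the first maximizer, and candidate order is by index).
    """
    n = D.shape[0]
    start = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(start), max(start)] if k >= 2 else [min(start)]
    mind = np.minimum(D[chosen[0]], D[chosen[-1]])
    mind[chosen] = -np.inf
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return np.array(sorted(chosen))


def kennard_stone(X: np.ndarray, ratio: float = 0.75) -> SplitResult:
    """Deterministic max-min split on Euclidean distances in X."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = _calib_size(n, ratio)
    D = squareform(pdist(X))
    calib = _greedy_maxmin(D, k)
    pred = np.setdiff1d(np.arange(n), calib)
    return SplitResult(calib, pred, "ks", ratio)


def spxy(X: np.ndarray, y: np.ndarray, ratio: float = 0.75) -> SplitResult:
    """Max-min split on the max-normalized joint X-y distance.

    A constant response contributes no distance; the split then falls back
    to plain Kennard-Stone.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    Dx = squareform(pdist(X))
    Dy = np.abs(y[:, None] - y[None, :])
    D = np.zeros_like(Dx)
    if Dx.max() > 0:
        D += Dx / Dx.max()
    if Dy.max() > 0:
        D += Dy / Dy.max()
    k = _calib_size(n, ratio)
    calib = _greedy_maxmin(D, k)
    pred = np.setdiff1d(np.arange(n), calib)
    return SplitResult(calib, pred, "spxy", ratio)
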