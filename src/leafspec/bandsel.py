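"""Wavelength (variable) selection: CARS, SPA, UVE, LARS.

All four selectors are pure functions of (X, y, config, seed): indices refer
to the columns of the matrix handed in, and a fixed seed reproduces the
result bit for bit.  Ranking ties break toward the lower band index.

CARS — competitive adaptive reweighted sampling.  A Monte-Carlo loop fits a
PLS model on a random row subset each iteration, ranks bands by the absolute
PLS regression coefficient, forces the retained count down an exponentially
decreasing schedule r_i = a*exp(-k*i) (from all bands to 2), resamples the
survivors with probability proportional to |coefficient|, and finally keeps
the iteration whose subset minimizes cross-validated RMSE.

SPA — successive projections algorithm.  Greedy forward selection that
repeatedly adds the band whose column has the largest norm after orthogonal
projection onto the complement of the span of the already-selected columns,
minimizing collinearity.  Deterministic given the starting band; auto mode
scores every start chain by PLS cross-validation.

UVE — uninformative variable elimination.  Appends known-noise columns,
computes leave-one-out PLS coefficient stability c_j = mean(b_j)/sd(b_j),
and keeps real bands whose |c_j| exceeds a quantile of the noise columns'
stabilities.

LARS — the first k variables to enter the least-angle regression path,
in entry order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import lars_path
from sklearn.model_selection import KFold

__all__ = [
    "SelectionResult",
    "cars_select",
    "spa_select",
    "uve_select",
    "lars_select",
]


@dataclass
class SelectionResult:
    """Selected band indices plus the selector's per-iteration diagnostics."""

    selected: np.ndarray
    trace: dict
    method: str
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        sel = np.asarray(self.selected)
        if sel.size == 0:
            raise ValueError("empty selection")
        if np.unique(sel).size != sel.size:
            raise ValueError("selection contains duplicates")
        self.selected = np.sort(sel)


def _pls_components(n_rows: int, n_cols: int, cap: int = 10) -> int:
    return max(1, min(cap, n_rows - 1, n_cols))


def _fit_pls_coef(X: np.ndarray, y: np.ndarray, cap: int = 10) -> np.ndarray:
    """Absolute-valued PLS regression coefficients, one per column."""
    ncomp = _pls_components(X.shape[0], X.shape[1], cap)
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X, y)
    return np.abs(pls.coef_).ravel()


def _cv_rmse_pls(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, cap: int = 10
) -> float:
    folds = min(folds, X.shape[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq = 0.0
    for tr, te in kf.split(X):
        ncomp = _pls_components(tr.size, X.shape[1], cap)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[tr], y[tr])
        pred = pls.predict(X[te]).ravel()
        sq += float(np.sum((y[te] - pred) ** 2))
    return float(np.sqrt(sq / X.shape[0]))


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    subsample: float = 0.8,
    cv_folds: int = 5,
    seed: int = 0,
    max_components: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    The exponentially decreasing function is pinned so iteration 1 retains
    every band and iteration ``runs`` retains 2 bands; the reweighted
    sampling draws exactly that count without replacement with probability
    proportional to |coefficient|, so the retained-count trace follows the
    closed form within rounding.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if runs < 2:
        raise ValueError("runs must be >= 2")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    if n < 2 * cv_folds:
        raise ValueError("need n >= 2 * cv_folds")
    rng = np.random.default_rng(seed)

    # r_i = a * exp(-k * i), r_1 = 1, r_runs = 2/B
    k = np.log(B / 2.0) / (runs - 1)
    a = np.exp(k)

    retained = np.arange(B)
    subsets, counts, rmses = [], [], []
    n_sub = max(2, int(round(subsample * n)))
    for i in range(1, runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        coef = _fit_pls_coef(X[np.ix_(rows, retained)], y[rows], max_components)
        # enforced descent: keep the EDF count by |coefficient| ranking
        n_keep = max(2, min(retained.size, int(round(a * np.exp(-k * i) * B))))
        order = np.lexsort((retained, -coef))  # ties -> lower band index
        retained = retained[order[:n_keep]]
        coef = coef[order[:n_keep]]
        # adaptive reweighting: resample the survivors by weight
        if coef.sum() > 0 and n_keep > 2:
            pick = rng.choice(
                n_keep, size=n_keep, replace=False, p=coef / coef.sum()
            )
            retained = np.sort(retained[pick])
        else:
            retained = np.sort(retained)
        rmse = _cv_rmse_pls(X[:, retained], y, cv_folds, seed, max_components)
        subsets.append(retained.copy())
        counts.append(retained.size)
        rmses.append(rmse)
    best = int(np.argmin(rmses))
    return SelectionResult(
        selected=subsets[best],
        trace={
            "retained_counts": np.array(counts),
            "cv_rmse": np.array(rmses),
            "best_iteration": best,
            "edf_a": a,
            "edf_k": k,
        },
        method="cars",
        config={
            "runs": runs,
            "subsample": subsample,
            "cv_folds": cv_folds,
            "max_components": max_components,
        },
        seed=seed,
    )


def _spa_chain(X: np.ndarray, first: int, k_max: int) -> tuple[list, list]:
    """One SPA forward chain from a given start band."""
    n, B = X.shape
    selected = [first]
    # residual columns, orthogonalized against the span of selections
    R = X.copy()
    norms_trace = []
    v = R[:, first].copy()
    nv = np.linalg.norm(v)
    for _ in range(k_max - 1):
        if nv > 1e-12:
            R = R - np.outer(v / nv, (v / nv) @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-10:
            break  # remaining columns are in the selected span
        selected.append(nxt)
        norms_trace.append(float(norms[nxt]))
        v = R[:, nxt].copy()
        nv = np.linalg.norm(v)
    return selected, norms_trace


def spa_select(
    X: np.ndarray,
    k_max: int,
    first_band: int | str = "auto",
    y: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Successive projections algorithm.

    ``first_band='auto'`` tries every start and keeps the chain with the
    best PLS cross-validated RMSE (requires ``y``); an integer start is
    fully deterministic.  Collinear columns are never co-selected: a column
    already in the selected span has zero projected norm and stops the
    chain.
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    if k_max > min(n, B):
        raise ValueError("k_max exceeds matrix rank bound")
    if first_band == "auto":
        if y is None:
            raise ValueError("auto start requires y")
        y = np.asarray(y, dtype=float).ravel()
        best_sel, best_rmse, best_trace, best_start = None, np.inf, None, None
        for start in range(B):
            sel, tr = _spa_chain(X, start, k_max)
            rmse = _cv_rmse_pls(X[:, sel], y, cv_folds, seed)
            if rmse < best_rmse:
                best_sel, best_rmse, best_trace, best_start = sel, rmse, tr, start
        return SelectionResult(
            selected=np.array(best_sel),
            trace={
                "projection_norms": np.array(best_trace),
                "cv_rmse": best_rmse,
                "start": best_start,
            },
            method="spa",
            config={"k_max": k_max, "first_band": "auto"},
            seed=seed,
        )
    sel, tr = _spa_chain(X, int(first_band), k_max)
    return SelectionResult(
        selected=np.array(sel),
        trace={"projection_norms": np.array(tr), "start": int(first_band)},
        method="spa",
        config={"k_max": k_max, "first_band": int(first_band)},
        seed=seed,
    )


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_noise: int | None = None,
    cutoff_quantile: float = 0.99,
    seed: int = 0,
    max_components: int = 10,
) -> SelectionResult:
    """Uninformative variable elimination against appended noise columns.

    Noise columns are uniform on [0, 1e-3 * max|X|].  Stability is the
    leave-one-out mean/sd ratio of the PLS coefficient; real bands must
    beat the ``cutoff_quantile`` of the noise bands' |stability|.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if n < 10:
        raise ValueError("UVE needs n >= 10")
    if n_noise is None:
        n_noise = B
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0, 1e-3 * np.abs(X).max(), size=(n, n_noise))
    Xa = np.hstack([X, noise])

    coefs = np.empty((n, B + n_noise))
    ncomp = _pls_components(n - 1, B + n_noise, max_components)
    for i in range(n):
        rows = np.delete(np.arange(n), i)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(Xa[rows], y[rows])
        coefs[i] = pls.coef_.ravel()
    sd = coefs.std(axis=0, ddof=1)
    sd[sd == 0] = np.finfo(float).tiny
    stability = coefs.mean(axis=0) / sd
    cutoff = np.quantile(np.abs(stability[B:]), cutoff_quantile)
    keep = np.where(np.abs(stability[:B]) > cutoff)[0]
    if keep.size == 0:
        raise ValueError("UVE eliminated every band; lower cutoff_quantile")
    return SelectionResult(
        selected=keep,
        trace={
            "stability": stability[:B],
            "noise_stability": stability[B:],
            "cutoff": float(cutoff),
        },
        method="uve",
        config={"n_noise": n_noise, "cutoff_quantile": cutoff_quantile},
        seed=seed,
    )


def lars_select(X: np.ndarray, y: np.ndarray, k: int) -> SelectionResult:
    """First ``k`` variables to enter the LARS path, in entry order.

    Columns are standardized internally; the returned ``selected`` is
    sorted, with the entry order preserved in the trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    B = X.shape[1]
    if k > B:
        raise ValueError("k exceeds band count")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    _, active, coefs = lars_path(Xs, y - y.mean(), method="lar", max_iter=k)
    entry_order = list(active[:k])
    if len(entry_order) < k:  # path exhausted early (rank deficiency)
        rest = [j for j in range(B) if j not in entry_order]
        entry_order += rest[: k - len(entry_order)]
    return SelectionResult(
        selected=np.array(entry_order),
        trace={"entry_order": np.array(entry_order), "coef_path": coefs},
        method="lars",
        config={"k": k},
    )
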