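"""Multivariate regressors (PLSR, RF, SVR, ELM), metrics, and the combo grid.

The grid runner evaluates every combination of

    preprocessing  {none, MA, SNV, D1}
  x band selection {CARS, SPA, LARS, UVE}
  x splitting      {Random, KS, SPXY}
  x regressor      {PLSR, RF, SVR, ELM}

per pigment, reporting calibration and prediction R^2 (RC2/RP2), RMSE
(RMSEC/RMSEP) and MAE for each.  Band selection and every fitted statistic
see calibration rows only — the prediction set never leaks into model
choice.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import bandsel, splitters
from .prep import PrepSpec, apply_prep

__all__ = [
    "FitReport",
    "GridResult",
    "metrics",
    "fit_plsr",
    "fit_rf",
    "fit_svr",
    "fit_elm",
    "run_grid",
]


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(RMSE, R^2, MAE) of predictions against observations.

    RMSE = sqrt(mean((y - yhat)^2)); R^2 = 1 - SSres/SStot with SStot taken
    about the mean of the observed values; MAE = mean(|y - yhat|).  A
    constant observed vector leaves R^2 undefined and raises.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        raise ValueError("constant y_true: R^2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    mae = float(np.mean(np.abs(resid)))
    return rmse, r2, mae


@dataclass(frozen=True)
class FitReport:
    """Calibration/prediction performance of one model on one pigment."""

    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    mae: float
    model: str = ""
    combo: str = ""

    @staticmethod
    def from_predictions(y_cal, p_cal, y_pred, p_pred, model="", combo=""):
        rmsec, rc2, _ = metrics(y_cal, p_cal)
        rmsep, rp2, mae = metrics(y_pred, p_pred)
        return FitReport(rc2, rmsec, rp2, rmsep, mae, model, combo)


# ---------------------------------------------------------------------------
# Regressors.  Each factory returns an object exposing predict(X) -> yhat.


def fit_plsr(Xc, yc, n_components: int | None = None, cv_folds: int = 5, seed: int = 0):
    """PLSR with the component count chosen by K-fold CV (cap 15)."""
    Xc = np.asarray(Xc, dtype=float)
    yc = np.asarray(yc, dtype=float).ravel()
    cap = max(1, min(15, Xc.shape[0] - 2, Xc.shape[1]))
    if n_components is None:
        folds = min(cv_folds, Xc.shape[0])
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        best, best_err = 1, np.inf
        for nc in range(1, cap + 1):
            err = 0.0
            for tr, te in kf.split(Xc):
                m = PLSRegression(n_components=min(nc, tr.size - 1), scale=False)
                m.fit(Xc[tr], yc[tr])
                err += float(np.sum((yc[te] - m.predict(Xc[te]).ravel()) ** 2))
            if err < best_err:
                best, best_err = nc, err
        n_components = best
    model = PLSRegression(n_components=min(n_components, cap), scale=False)
    model.fit(Xc, yc)

    class _P:
        def predict(self, X):
            return model.predict(np.asarray(X, dtype=float)).ravel()

    return _P()


def fit_rf(Xc, yc, n_trees: int = 500, seed: int = 0):
    """Random forest with ``n_trees`` trees."""
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(np.asarray(Xc, dtype=float), np.asarray(yc, dtype=float).ravel())

    class _P:
        def predict(self, X):
            return model.predict(np.asarray(X, dtype=float))

    return _P()


def fit_svr(Xc, yc, cv_folds: int = 3, seed: int = 0):
    """RBF-kernel SVR; (C, gamma) picked by CV on a small grid.

    Inputs are standardized with calibration-set statistics only.
    """
    Xc = np.asarray(Xc, dtype=float)
    yc = np.asarray(yc, dtype=float).ravel()
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xc - mu) / sd
    g0 = 1.0 / (Xs.shape[1] * max(Xs.var(), 1e-12))  # 'scale' heuristic
    folds = min(cv_folds, Xs.shape[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best, best_err = None, np.inf
    for C in (1.0, 10.0, 100.0):
        for gm in (0.1 * g0, g0, 10 * g0):
            err = 0.0
            for tr, te in kf.split(Xs):
                m = SVR(kernel="rbf", C=C, gamma=gm)
                m.fit(Xs[tr], yc[tr])
                err += float(np.sum((yc[te] - m.predict(Xs[te])) ** 2))
            if err < best_err:
                best, best_err = (C, gm), err
    model = SVR(kernel="rbf", C=best[0], gamma=best[1])
    model.fit(Xs, yc)

    class _P:
        def predict(self, X):
            X = (np.asarray(X, dtype=float) - mu) / sd
            return model.predict(X)

    return _P()


def fit_elm(Xc, yc, n_hidden: int = 200, seed: int = 0):
    """Extreme learning machine: one sigmoid hidden layer.

    Hidden weights and biases are drawn once from the seeded generator and
    never trained; output weights solve the least-squares problem on the
    hidden activations by pseudoinverse.  With at least as many hidden
    units as distinct calibration samples this interpolates the
    calibration set.
    """
    Xc = np.asarray(Xc, dtype=float)
    yc = np.asarray(yc, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
    sd[sd == 0] = 1.0
    W = rng.normal(0, 1.0, size=(Xc.shape[1], n_hidden))
    b = rng.uniform(-1, 1, size=n_hidden)

    def hidden(X):
        Z = ((np.asarray(X, dtype=float) - mu) / sd) @ W + b
        return 1.0 / (1.0 + np.exp(-Z))

    beta = np.linalg.pinv(hidden(Xc)) @ yc

    class _P:
        def predict(self, X):
            return hidden(X) @ beta

    return _P()


_MODEL_FITTERS = {"plsr": fit_plsr, "rf": fit_rf, "svr": fit_svr, "elm": fit_elm}


# ---------------------------------------------------------------------------
# Combination grid


@dataclass
class GridResult:
    """Tidy table of FitReports over the full combination grid.

    ``selections`` maps (prep-selector-split, pigment) to the band indices
    chosen on the calibration rows, for audit (e.g. leakage checks).
    """

    table: pd.DataFrame
    best: dict  # pigment -> row (as dict)
    failures: list = field(default_factory=list)
    selections: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _stage_seed(base: int, *parts) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    h = hashlib.sha256(("|".join(map(str, parts)) + f"#{base}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _select_bands(method: str, Xc, yc, seed: int, k_sel: int, cars_runs: int):
    if method == "cars":
        return bandsel.cars_select(Xc, yc, runs=cars_runs, seed=seed)
    if method == "spa":
        k = min(k_sel, Xc.shape[0] - 1, Xc.shape[1])
        return bandsel.spa_select(Xc, k_max=k, first_band=0)
    if method == "uve":
        return bandsel.uve_select(Xc, yc, seed=seed)
    if method == "lars":
        return bandsel.lars_select(Xc, yc, k=min(k_sel, Xc.shape[1]))
    if method == "none":
        return bandsel.SelectionResult(
            selected=np.arange(Xc.shape[1]), trace={}, method="none"
        )
    raise ValueError(f"unknown selector {method!r}")


def _split(method: str, X, y, ratio: float, seed: int):
    if method == "random":
        return splitters.random_split(X.shape[0], ratio, seed)
    if method == "ks":
        return splitters.kennard_stone(X, ratio)
    if method == "spxy":
        return splitters.spxy(X, y, ratio)
    raise ValueError(f"unknown split method {method!r}")


def run_grid(
    spectra: np.ndarray,
    targets: np.ndarray,
    wavelengths: np.ndarray,
    preps: tuple = ("none", "ma", "snv", "d1"),
    selectors: tuple = ("cars", "spa", "lars", "uve"),
    splits: tuple = ("random", "ks", "spxy"),
    models: tuple = ("plsr", "rf", "svr", "elm"),
    pigments: tuple = ("chla", "chlb", "car", "tpc"),
    ratio: float = 0.75,
    seed: int = 0,
    k_sel: int = 20,
    cars_runs: int = 50,
) -> GridResult:
    """Run the preprocessing x selection x split x model grid per pigment.

    For each combination: preprocess all spectra (fit-free), split, select
    bands on calibration rows only, fit on calibration, evaluate both sets.
    Failures are recorded per combo and the grid continues.  Deterministic
    given ``seed``: every stochastic stage draws from a seed derived from
    the global seed and the combo tag.
    """
    targets = np.asarray(targets, dtype=float)
    pig_col = {"chla": 0, "chlb": 1, "car": 2, "tpc": 3}
    rows, failures = [], []
    selections = {}
    for prep_name in preps:
        Xp = apply_prep(PrepSpec(method=prep_name), spectra, wavelengths)
        for pig in pigments:
            y = targets[:, pig_col[pig]]
            for split_name in splits:
                sp = _split(
                    split_name, Xp, y, ratio, _stage_seed(seed, "split", split_name, pig)
                )
                Xc, yc = Xp[sp.calib_idx], y[sp.calib_idx]
                Xv, yv = Xp[sp.pred_idx], y[sp.pred_idx]
                for sel_name in selectors:
                    combo_base = f"{prep_name}-{sel_name}-{split_name}"
                    try:
                        sel = _select_bands(
                            sel_name,
                            Xc,
                            yc,
                            _stage_seed(seed, "select", combo_base, pig),
                            k_sel,
                            cars_runs,
                        )
                    except Exception as e:  # degenerate combos stay visible
                        failures.append((f"{combo_base}", pig, repr(e)))
                        continue
                    selections[(combo_base, pig)] = sel.selected.copy()
                    for model_name in models:
                        combo = f"{combo_base}-{model_name}"
                        try:
                            fitter = _MODEL_FITTERS[model_name]
                            pred = fitter(
                                Xc[:, sel.selected],
                                yc,
                                seed=_stage_seed(seed, "fit", combo, pig),
                            )
                            rep = FitReport.from_predictions(
                                yc,
                                pred.predict(Xc[:, sel.selected]),
                                yv,
                                pred.predict(Xv[:, sel.selected]),
                                model=model_name,
                                combo=combo,
                            )
                        except Exception as e:
                            failures.append((combo, pig, repr(e)))
                            continue
                        rows.append(
                            {
                                "combo": combo,
                                "pigment": pig,
                                "prep": prep_name,
                                "selector": sel_name,
                                "split": split_name,
                                "model": model_name,
                                "n_bands_selected": int(sel.selected.size),
                                "rc2": rep.rc2,
                                "rmsec": rep.rmsec,
                                "rp2": rep.rp2,
                                "rmsep": rep.rmsep,
                                "mae": rep.mae,
                            }
                        )
    table = pd.DataFrame(rows)
    best = {}
    if len(table):
        for pig in pigments:
            sub = table[table.pigment == pig]
            if len(sub):
                best[pig] = sub.loc[sub.rp2.idxmax()].to_dict()
    return GridResult(table=table, best=best, failures=failures, selections=selections)
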