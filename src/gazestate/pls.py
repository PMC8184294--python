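"""PLS1 regression of automation state on oculometric indicators.

The state code (+1 manual, -1 automated) is regressed on p >> n,
strongly collinear indicator matrices with single-response partial least
squares, computed by NIPALS: each component's weight vector is X'y
normalised to unit length, scores are t = Xw, X- and y-loadings are
least-squares projections on t, and X and y are deflated before the next
component. With as many components as the rank of a full-rank X the
coefficients coincide with ordinary least squares; with fewer, PLS
shrinks along directions of low covariance with y.

Model capacity is chosen by leave-one-out cross-validation of the mean
squared error of prediction (MSEP), re-standardising the predictors
inside every fold so no information leaks from the held-out unit.
Indicator selection is backward elimination: repeatedly drop the
indicator with the smallest absolute standardised coefficient and keep
the candidate set whose leave-one-out MSEP is lowest (ties favour the
smaller set). A VIP-threshold alternative (drop indicators with
variable importance in projection below 1) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, SchemaError
from .indicators import DesignMatrix, standardize

__all__ = [
    "PlsModel",
    "CvReport",
    "fit_pls1",
    "predict_scores",
    "loo_msep",
    "select_components",
    "select_indicators",
    "msep",
    "vip_scores",
]

_EPS = np.finfo(float).eps


def msep(y, yhat) -> float:
    """Mean squared error of prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class PlsModel:
    """Fitted PLS1 model on the standardised indicator scale.

    ``coefficients`` map standardised indicators to the response;
    ``intercept`` is on the original response scale (the training mean of
    y, since predictors are centred). ``center``/``scale`` are the
    training standardisation parameters, carried so the model can score
    raw indicator rows.
    """

    selected: tuple[str, ...]
    coefficients: pd.Series
    intercept: float
    n_components: int
    weights: np.ndarray = field(repr=False)
    x_loadings: np.ndarray = field(repr=False)
    y_loadings: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    center: pd.Series | None = None
    scale: pd.Series | None = None
    mode: str | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "selected": list(self.selected),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "n_components": int(self.n_components),
            "center": None
            if self.center is None
            else {k: float(v) for k, v in self.center.items()},
            "scale": None
            if self.scale is None
            else {k: float(v) for k, v in self.scale.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        selected = tuple(d["selected"])
        k = int(d["n_components"])
        p = len(selected)
        return cls(
            selected=selected,
            coefficients=pd.Series(d["coefficients"], dtype=float)[list(selected)],
            intercept=float(d["intercept"]),
            n_components=k,
            weights=np.zeros((p, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            scores=np.zeros((0, 0)),
            center=None if d.get("center") is None else pd.Series(d["center"], dtype=float),
            scale=None if d.get("scale") is None else pd.Series(d["scale"], dtype=float),
            mode=d.get("mode"),
        )


@dataclass(frozen=True)
class CvReport:
    """Leave-one-out cross-validation summary.

    ``msep_by_ncomp`` maps each candidate component count to its LOO
    MSEP; ``chosen_ncomp`` is the argmin (ties to the smallest count);
    ``per_unit_predictions`` are the left-out predictions at the chosen
    count, aligned with the training rows.
    """

    msep_by_ncomp: dict[int, float]
    chosen_ncomp: int
    msep: float
    per_unit_predictions: np.ndarray
    excluded_units: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "msep_by_ncomp": {int(k): float(v) for k, v in self.msep_by_ncomp.items()},
            "chosen_ncomp": int(self.chosen_ncomp),
            "msep": float(self.msep),
        }


def _nipals(X: np.ndarray, y: np.ndarray, ncomp: int):
    """Core NIPALS decomposition for one response on centred data.

    Returns weights W, x-loadings P, y-loadings q, scores T and the
    coefficient path B[:, k] (coefficients using the first k+1
    components). Stops early if the residual covariance X'y vanishes.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    R = np.zeros((p, ncomp))  # W (P'W)^{-1}, built recursively
    B = np.zeros((p, ncomp))
    b = np.zeros(p)
    actual = 0
    for a in range(ncomp):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= 1e3 * _EPS * max(1.0, np.linalg.norm(yd)):
            break  # nothing left to extract
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e3 * _EPS:
            break
        pa = Xd.T @ t / tt
        qa = float(t @ yd) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        W[:, a], P[:, a], q[a], T[:, a], R[:, a] = w, pa, qa, t, r
        b = b + qa * r
        B[:, a] = b
        actual += 1
    return W[:, :actual], P[:, :actual], q[:actual], T[:, :actual], B[:, :actual]


def fit_pls1(X, y, ncomp: int, *, mode: str | None = None) -> PlsModel:
    """Fit a PLS1 model on a standardised design.

    ``X`` may be a standardised :class:`DesignMatrix` (its centring and
    scaling are carried into the model), a DataFrame, or a plain array.
    ``ncomp`` must not exceed min(rows - 1, columns); if the response
    covariance is exhausted earlier, the model stops with fewer
    components (recorded in ``n_components``).
    """
    center = scale = None
    if isinstance(X, DesignMatrix):
        center, scale, mode = X.center, X.scale, mode or X.mode
        names = X.columns
        Xa = X.values.to_numpy(dtype=float)
    elif isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows")
    if not 1 <= ncomp <= min(n - 1, p):
        raise InsufficientDataError(
            f"ncomp={ncomp} out of range for a {n}x{p} design"
        )
    ybar = float(y.mean())
    W, P, q, T, B = _nipals(Xa, y - ybar, ncomp)
    if B.shape[1] == 0:
        coef = np.zeros(p)
        k = 0
    else:
        coef = B[:, -1]
        k = B.shape[1]
    return PlsModel(
        selected=tuple(names),
        coefficients=pd.Series(coef, index=names),
        intercept=ybar,
        n_components=k,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        center=center,
        scale=scale,
        mode=mode,
    )


def predict_scores(model: PlsModel, X_new) -> np.ndarray:
    """Continuous state scores for new units.

    Raw indicator rows are standardised with the training parameters when
    the model carries them; already-standardised input is scored as-is.
    Extra columns are ignored; a missing selected indicator is an error.
    """
    if isinstance(X_new, DesignMatrix):
        X_new = X_new.values
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.selected if c not in X_new.columns]
        if missing:
            raise SchemaError(f"missing selected indicators: {missing[:5]}")
        Z = X_new[list(model.selected)].astype(float)
    else:
        Z = pd.DataFrame(np.asarray(X_new, dtype=float), columns=list(model.selected))
    if model.center is not None:
        Z = (Z - model.center[list(model.selected)]) / model.scale[list(model.selected)]
    return model.intercept + Z.to_numpy() @ model.coefficients.to_numpy()


def _max_ncomp(n: int, p: int, requested: int | None) -> int:
    cap = min(10, n - 2) if requested is None else requested
    return max(1, min(cap, n - 2, p))


def loo_msep(X, y, max_ncomp: int | None = None) -> CvReport:
    """Leave-one-out MSEP for every candidate component count.

    Each fold re-standardises the remaining units (columns constant
    within the fold are dropped there), refits, and predicts the held-out
    unit; MSEP(k) is the mean squared left-out error using k components
    (folds supporting fewer components use their maximum).
    """
    values, y = _as_frame(X, y)
    n, p = values.shape
    if n < 3:
        raise InsufficientDataError("leave-one-out needs at least 3 units")
    kmax = _max_ncomp(n, p, max_ncomp)
    preds = np.full((n, kmax), np.nan)
    excluded = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = values.iloc[mask].reset_index(drop=True)
        try:
            dm = standardize(
                DesignMatrix(mode="fold", unit_ids=tuple(range(n - 1)), values=train)
            )
        except DegenerateDataError:
            excluded.append(i)
            warnings.warn(f"fold {i}: degenerate design, unit excluded", stacklevel=2)
            continue
        yf = y[mask]
        kf = min(kmax, len(dm.columns), n - 2)
        Xi = dm.transform(values.iloc[[i]]).to_numpy()[0]
        # left-out prediction at every component count via the coefficient path
        _, _, _, _, B = _nipals(
            dm.values.to_numpy(dtype=float), yf - yf.mean(), kf
        )
        for k in range(kmax):
            kk = min(k, B.shape[1] - 1)
            if kk < 0:
                preds[i, k] = yf.mean()
            else:
                preds[i, k] = yf.mean() + Xi @ B[:, kk]
    ok = ~np.isnan(preds[:, 0])
    if ok.sum() < 3:
        raise DegenerateDataError("too many degenerate folds for leave-one-out")
    msep_by = {
        k + 1: float(np.mean((y[ok] - preds[ok, k]) ** 2)) for k in range(kmax)
    }
    chosen = min(msep_by, key=lambda k: (msep_by[k], k))
    return CvReport(
        msep_by_ncomp=msep_by,
        chosen_ncomp=chosen,
        msep=msep_by[chosen],
        per_unit_predictions=preds[:, chosen - 1],
        excluded_units=tuple(excluded),
    )


def select_components(X, y, max_ncomp: int | None = None) -> int:
    """Component count minimising leave-one-out MSEP (ties to fewer)."""
    return loo_msep(X, y, max_ncomp).chosen_ncomp


def vip_scores(model: PlsModel) -> pd.Series:
    """Variable importance in projection of each indicator."""
    W, T, q = model.weights, model.scores, model.y_loadings
    if W.shape[1] == 0:
        return pd.Series(0.0, index=list(model.selected))
    ss = (q**2) * np.einsum("ij,ij->j", T, T)  # explained y-variance per component
    wnorm2 = (W / np.maximum(np.linalg.norm(W, axis=0), _EPS)) ** 2
    p = W.shape[0]
    vip = np.sqrt(p * (wnorm2 @ ss) / ss.sum())
    return pd.Series(vip, index=list(model.selected))


def _as_frame(X, y) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(X, DesignMatrix):
        values = X.values
    elif isinstance(X, pd.DataFrame):
        values = X
    else:
        Xa = np.asarray(X, dtype=float)
        values = pd.DataFrame(Xa, columns=[f"x{i}" for i in range(Xa.shape[1])])
    y = np.asarray(y, dtype=float)
    if len(values) != len(y):
        raise ValueError("y length must match the number of rows")
    return values.reset_index(drop=True), y


def select_indicators(
    X,
    y,
    *,
    max_ncomp: int | None = None,
    strategy: str = "backward",
) -> tuple[list[str], PlsModel, CvReport]:
    """Reduce the indicator set to those relevant for prediction.

    ``backward`` walks the full elimination path (drop the smallest
    absolute standardised coefficient at each step, re-selecting the
    component count by LOO) and returns the candidate set with the lowest
    LOO MSEP; exact ties are broken toward fewer indicators, then toward
    canonical column order of the drop. ``vip`` performs a single
    variable-importance cut at VIP >= 1.

    Returns the selected names, the final model refit on the full data
    restricted to them, and that refit's cross-validation report.
    """
    values, y = _as_frame(X, y)
    mode = X.mode if isinstance(X, DesignMatrix) else None
    if strategy == "vip":
        return _select_vip(values, y, max_ncomp, mode)
    if strategy != "backward":
        raise SchemaError(f"unknown selection strategy: {strategy!r}")

    cols = list(values.columns)
    best: tuple[float, int, list[str], PlsModel, CvReport] | None = None
    while True:
        model, report = _fit_subset(values, y, cols, max_ncomp, mode)
        cand = (report.msep, len(cols), list(cols), model, report)
        if best is None or _better(cand, best):
            best = cand
        if len(cols) <= 1:
            break
        # Rank drops with the full-capacity model: at the CV-chosen (small)
        # component count coefficients are shrunk toward the X'y direction
        # and ranking degenerates to marginal correlation, discarding
        # indicators whose relevance is multivariate.
        coefs = _ranking_fit(values, y, cols, max_ncomp, mode).coefficients.abs()
        # absent columns (dropped as constant) have no coefficient: drop first
        ranked = [(coefs.get(c, -1.0), -cols.index(c), c) for c in cols]
        drop = min(ranked)[2]
        cols = [c for c in cols if c != drop]
    _, _, sel, model, report = best
    return sel, model, report


def _ranking_fit(values, y, cols, max_ncomp, mode) -> PlsModel:
    sub = values[cols]
    dm = standardize(
        DesignMatrix(mode=mode or "subset", unit_ids=tuple(range(len(sub))), values=sub)
    )
    k = _max_ncomp(len(sub), len(dm.columns), max_ncomp)
    return fit_pls1(dm, y, k, mode=mode)


def _better(cand, best) -> bool:
    tol = 1e-12 * (1.0 + best[0])
    if cand[0] < best[0] - tol:
        return True
    if cand[0] <= best[0] + tol and cand[1] < best[1]:
        return True
    return False


def _fit_subset(values, y, cols, max_ncomp, mode):
    sub = values[cols]
    report = loo_msep(sub, y, max_ncomp)
    dm = standardize(
        DesignMatrix(mode=mode or "subset", unit_ids=tuple(range(len(sub))), values=sub)
    )
    k = min(report.chosen_ncomp, len(dm.columns), len(sub) - 1)
    model = fit_pls1(dm, y, k, mode=mode)
    return model, report


def _select_vip(values, y, max_ncomp, mode):
    full_model, full_report = _fit_subset(values, y, list(values.columns), max_ncomp, mode)
    vip = vip_scores(full_model)
    keep = [c for c in values.columns if vip.get(c, 0.0) >= 1.0]
    if not keep or len(keep) == len(values.columns):
        return list(full_model.selected), full_model, full_report
    model, report = _fit_subset(values, y, keep, max_ncomp, mode)
    return keep, model, report
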