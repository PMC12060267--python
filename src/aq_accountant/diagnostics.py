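"""Model interrogation: concurvity screening, k-fold CV, fit metrics,
and permutation variable importance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .gam import CubicRegressionSpline, SplineGAM


class SelectionError(ValueError):
    pass


def performance_metrics(observed, predicted) -> dict:
    """R² (squared Pearson correlation), mean bias, and RMSE.

    MB = mean(predicted - observed); RMSE on the same difference. With a
    zero-variance input R² is undefined and returned as NaN with a flag.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    diff = pred - obs
    mb = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    undefined = bool(np.std(obs) == 0 or np.std(pred) == 0)
    r2 = float("nan") if undefined else float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return {"r2": r2, "mb": mb, "rmse": rmse, "r2_undefined": undefined}


@dataclass
class CvReport:
    per_fold: pd.DataFrame       # fold, n_test, r2, mb, rmse
    pooled: dict                 # metrics on concatenated out-of-fold predictions
    fold_assignment: np.ndarray  # fold index per row
    oof_predictions: np.ndarray


def cross_validate(model: SplineGAM, X: pd.DataFrame, y, n_folds: int = 10, seed: int = 0) -> CvReport:
    """k-fold CV with random fold assignment; each row is tested once.

    Pooled metrics are computed on the concatenated out-of-fold
    predictions, so every observation contributes exactly once.
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, n_folds)):
        if len(idx) < 2:
            raise ValueError(f"fold {f} has fewer than 2 rows")
        assignment[idx] = f
    oof = np.full(n, np.nan)
    rows = []
    for f in range(n_folds):
        test = assignment == f
        est = clone(model).fit(X.loc[~test], y[~test])
        pred = est.predict(X.loc[test])
        oof[test] = pred
        m = performance_metrics(y[test], pred)
        rows.append({"fold": f, "n_test": int(test.sum()), **{k: m[k] for k in ("r2", "mb", "rmse")}})
    pooled = performance_metrics(y, oof)
    return CvReport(
        per_fold=pd.DataFrame(rows),
        pooled=pooled,
        fold_assignment=assignment,
        oof_predictions=oof,
    )


def permutation_importance(
    model: SplineGAM,
    X: pd.DataFrame,
    y,
    indicators=None,
    n_shuffles: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Correlation drop when one indicator's column is shuffled.

    Importance of indicator v = mean over shuffles of
    ``corr(y, yhat_original) - corr(y, yhat_with_v_shuffled)``.
    An indicator the model does not use has importance exactly 0 (its
    column never enters the design), and is reported as such without
    recomputation.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    y = np.asarray(y, dtype=float)
    used = set(model._required_columns())
    if indicators is None:
        indicators = sorted(used)
    for v in indicators:
        if v not in X.columns:
            raise KeyError(f"indicator {v!r} not present in the data")
    baseline = float(np.corrcoef(y, model.predict(X))[0, 1])
    rng = np.random.default_rng(seed)
    out = {}
    for v in indicators:
        if v not in used:
            out[v] = 0.0
            continue
        drops = []
        for _ in range(n_shuffles):
            Xs = X.copy()
            Xs[v] = rng.permutation(Xs[v].to_numpy())
            drops.append(baseline - float(np.corrcoef(y, model.predict(Xs))[0, 1]))
        out[v] = float(np.mean(drops))
    return pd.Series(out, name="importance")


def concurvity(u, v, k: int = 10) -> float:
    """R² of one covariate regressed on the other's spline basis expansion."""
    u = np.asarray(u, dtype=float)
    basis, _ = CubicRegressionSpline(k=min(k, max(4, len(v) - 1))).fit(np.asarray(v, float)).transform(np.asarray(v, float))
    D = np.column_stack([np.ones(len(u)), basis])
    coef, *_ = np.linalg.lstsq(D, u, rcond=None)
    resid = u - D @ coef
    tss = float(np.sum((u - u.mean()) ** 2))
    if tss == 0:
        return 1.0
    return 1.0 - float(resid @ resid) / tss


def select_features(
    candidates,
    X: pd.DataFrame,
    y,
    threshold: float = 0.8,
    k: int = 10,
):
    """Greedy concurvity screen over candidate smooth covariates.

    For every pair whose concurvity (max over both regression directions)
    exceeds ``threshold``, the member less correlated (absolute Pearson)
    with the response is dropped; ties break alphabetically (the later
    name is dropped). Deterministic: pairs are visited in sorted order.
    """
    if len(candidates) < 2:
        raise SelectionError("need at least two candidate variables")
    if not 0 < threshold <= 1:
        raise SelectionError("threshold must lie in (0, 1]")
    y = np.asarray(y, dtype=float)
    cands = sorted(candidates)
    corr = {
        v: abs(float(np.corrcoef(y, X[v].to_numpy(dtype=float))[0, 1])) for v in cands
    }
    retained = list(cands)
    dropped_log = []
    for i, u in enumerate(cands):
        for v in cands[i + 1 :]:
            if u not in retained or v not in retained:
                continue
            c = max(
                concurvity(X[u].to_numpy(), X[v].to_numpy(), k),
                concurvity(X[v].to_numpy(), X[u].to_numpy(), k),
            )
            if c > threshold:
                if corr[u] > corr[v]:
                    loser = v
                elif corr[u] < corr[v]:
                    loser = u
                else:
                    loser = max(u, v)  # alphabetical tie-break
                retained.remove(loser)
                dropped_log.append({"pair": (u, v), "concurvity": c, "dropped": loser})
    if not retained:
        raise SelectionError("concurvity screen dropped every candidate")
    return retained, dropped_log
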