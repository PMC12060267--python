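"""Additive penalized-spline models for daily source contributions.

The regression links a source's daily PM2.5 contribution to sector
emissions, surface meteorology, and categorical calendar structure:

    y_t = a + sum_j f_j(x_jt) + sum_c beta_c[level_c(t)] + e_t

Each ``f_j`` is a cubic B-spline with knots at observed quantiles and an
integrated-squared-second-derivative penalty; smoothing parameters are
chosen by generalized cross-validation (REML is available as an option).
Identifiability comes from column-centering every smooth and categorical
block against the training data, leaving a single free intercept.

Predictions outside a smooth covariate's training range use a linear
extension of the spline beyond the boundary knots and are flagged, since
counterfactual emissions routinely exceed anything seen in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from sklearn.base import BaseEstimator, RegressorMixin


class GamFitError(RuntimeError):
    """Raised when the penalized design is rank deficient or unusable."""


class CubicRegressionSpline:
    """Cubic B-spline basis with quantile knots and a curvature penalty.

    Parameters
    ----------
    k : int
        Number of basis functions (>= 4); ``k - 4`` interior knots are
        placed at evenly spaced quantiles of the training covariate.
    """

    degree = 3

    def __init__(self, k: int = 10):
        if k < 4:
            raise ValueError(f"cubic spline basis needs k >= 4, got {k}")
        self.k = int(k)

    def fit(self, x: np.ndarray) -> "CubicRegressionSpline":
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("covariate contains non-finite values")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise GamFitError("covariate is constant; cannot build spline basis")
        m = self.k - 4
        if m > 0:
            qs = np.linspace(0, 1, m + 2)[1:-1]
            interior = np.unique(np.quantile(x, qs))
            interior = interior[(interior > lo) & (interior < hi)]
        else:
            interior = np.array([])
        self.knots_ = np.concatenate([[lo] * 4, interior, [hi] * 4])
        self.n_basis_ = len(interior) + 4
        self.lo_, self.hi_ = lo, hi
        c = np.eye(self.n_basis_)
        self._spl = BSpline(self.knots_, c, self.degree)
        self._d1 = self._spl.derivative(1)
        self._d2 = self._spl.derivative(2)
        return self

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix and a boolean extrapolation flag per row.

        Outside ``[lo, hi]`` the basis is extended linearly from the
        boundary: ``B(x) = B(b) + B'(b) (x - b)``.
        """
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.lo_, self.hi_)
        design = self._spl(xc)
        low = x < self.lo_
        high = x > self.hi_
        if low.any():
            design[low] += np.outer(x[low] - self.lo_, self._d1(self.lo_))
        if high.any():
            design[high] += np.outer(x[high] - self.hi_, self._d1(self.hi_))
        return design, low | high

    def penalty(self) -> np.ndarray:
        """Integrated squared second derivative, exact via 2-point Gauss.

        The second derivative of a cubic B-spline is piecewise linear, so
        its pairwise products are quadratic and a 2-point rule per
        inter-knot interval integrates them exactly.
        """
        nodes, weights = leggauss(2)
        P = np.zeros((self.n_basis_, self.n_basis_))
        breaks = np.unique(self.knots_)
        for a, b in zip(breaks[:-1], breaks[1:]):
            half = (b - a) / 2.0
            mid = (a + b) / 2.0
            for t, w in zip(nodes, weights):
                d2 = self._d2(mid + half * t)
                P += (w * half) * np.outer(d2, d2)
        return P

    def to_dict(self) -> dict:
        return {"k": self.k, "knots": self.knots_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CubicRegressionSpline":
        self = cls(k=d["k"])
        knots = np.asarray(d["knots"], dtype=float)
        self.knots_ = knots
        self.n_basis_ = len(knots) - 8 + 4
        self.lo_, self.hi_ = float(knots[0]), float(knots[-1])
        self._spl = BSpline(knots, np.eye(self.n_basis_), self.degree)
        self._d1 = self._spl.derivative(1)
        self._d2 = self._spl.derivative(2)
        return self


@dataclass
class _TermBlock:
    """Column block of the assembled design matrix.

    Smooth blocks carry the sum-to-zero constraint matrix ``Z`` (an
    orthonormal null-space basis of the training column-sum vector):
    B-spline columns form a partition of unity, so without dropping that
    dimension the design would be exactly rank deficient against the
    intercept.
    """

    name: str
    kind: str  # "intercept" | "smooth" | "categorical"
    sl: slice
    basis: CubicRegressionSpline | None = None
    levels: list | None = None
    center: np.ndarray | None = None
    Z: np.ndarray | None = None


@dataclass
class GamSpec:
    """Declarative model specification for one source factor.

    ``smooth_terms`` maps covariate name to basis size ``k``; categorical
    terms are calendar indicators (``day_of_week``, ``month``) carried as
    integer columns of the data table.
    """

    response: str
    smooth_terms: dict[str, int] = field(default_factory=dict)
    categorical_terms: list[str] = field(default_factory=lambda: ["day_of_week", "month"])
    concurvity_threshold: float = 0.8

    def __post_init__(self):
        for v, k in self.smooth_terms.items():
            if k < 4:
                raise ValueError(f"smooth term {v!r}: basis size must be >= 4, got {k}")

    def build(self, method: str = "gcv") -> "SplineGAM":
        return SplineGAM(
            smooth_terms=dict(self.smooth_terms),
            categorical_terms=list(self.categorical_terms),
            method=method,
        )


class SplineGAM(BaseEstimator, RegressorMixin):
    """Gaussian additive model with penalized cubic regression splines.

    Parameters
    ----------
    smooth_terms : dict[str, int]
        Covariate name -> basis dimension ``k`` (default 10 if a list of
        names is given instead).
    categorical_terms : sequence of str
        Integer-coded categorical columns (e.g. ``day_of_week``,
        ``month``); encoded as centered treatment contrasts, unpenalized.
    method : {"gcv", "reml"}
        Smoothing-parameter selection criterion.
    lam : float, dict or None
        Fixed smoothing parameter(s); ``None`` selects by `method`.
    lam_grid : (lo, hi, num)
        log10 grid searched coordinate-wise before the simplex polish.
    polish : bool
        Run a Nelder--Mead refinement after the grid search.

    Attributes
    ----------
    coef_ : ndarray            penalized least-squares coefficients
    lambda_ : dict             selected smoothing parameter per smooth
    edf_ : float               total effective degrees of freedom
    edf_per_term_ : dict       edf per smooth term
    sigma2_ : float            residual variance estimate RSS/(n - edf)
    cov_ : ndarray             Bayesian posterior covariance of coef_
    n_dropped_ : int           rows removed for missing values
    """

    def __init__(
        self,
        smooth_terms=None,
        categorical_terms=("day_of_week", "month"),
        k: int = 10,
        method: str = "gcv",
        lam=None,
        lam_grid=(-4.0, 8.0, 25),
        polish: bool = True,
    ):
        self.smooth_terms = smooth_terms
        self.categorical_terms = categorical_terms
        self.k = k
        self.method = method
        self.lam = lam
        self.lam_grid = lam_grid
        self.polish = polish

    # ------------------------------------------------------------------
    # design assembly

    def _smooth_spec(self) -> dict[str, int]:
        st = self.smooth_terms or {}
        if not isinstance(st, dict):
            st = {v: self.k for v in st}
        return st

    def _required_columns(self) -> list[str]:
        return list(self._smooth_spec()) + list(self.categorical_terms or [])

    def _assemble_training(self, X: pd.DataFrame):
        blocks: list[_TermBlock] = [_TermBlock("intercept", "intercept", slice(0, 1))]
        cols = [np.ones((len(X), 1))]
        penalties: list[tuple[slice, np.ndarray]] = []
        pos = 1
        for var, k in self._smooth_spec().items():
            basis = CubicRegressionSpline(k=k).fit(X[var].to_numpy())
            design, _ = basis.transform(X[var].to_numpy())
            # sum-to-zero constraint: reparameterize onto the null space
            # of the column-sum vector so the smooth is identifiable
            # against the intercept
            Z = null_space(design.sum(axis=0, keepdims=True))
            width = Z.shape[1]
            sl = slice(pos, pos + width)
            blocks.append(_TermBlock(var, "smooth", sl, basis=basis, Z=Z))
            cols.append(design @ Z)
            penalties.append((sl, Z.T @ basis.penalty() @ Z))
            pos += width
        for var in self.categorical_terms or []:
            levels = sorted(pd.unique(X[var].dropna()))
            if len(levels) < 2:
                warnings.warn(f"categorical term {var!r} has a single level; skipped")
                continue
            design = self._dummies(X[var].to_numpy(), levels)
            center = design.mean(axis=0)
            sl = slice(pos, pos + design.shape[1])
            blocks.append(_TermBlock(var, "categorical", sl, levels=levels, center=center))
            cols.append(design - center)
            pos += design.shape[1]
        return np.hstack(cols), blocks, penalties

    @staticmethod
    def _dummies(values, levels) -> np.ndarray:
        # treatment contrasts: first level is the reference
        codes = pd.Categorical(values, categories=levels).codes
        if (codes < 0).any():
            bad = pd.unique(np.asarray(values)[codes < 0])
            raise ValueError(f"unseen categorical level(s) {list(bad)[:5]}")
        out = np.zeros((len(codes), len(levels) - 1))
        pos = codes > 0
        out[np.flatnonzero(pos), codes[pos] - 1] = 1.0
        return out

    def _design(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix for new data plus per-row extrapolation flags."""
        n = len(X)
        D = np.zeros((n, self.n_coef_))
        flags = np.zeros(n, dtype=bool)
        for blk in self.blocks_:
            if blk.kind == "intercept":
                D[:, blk.sl] = 1.0
            elif blk.kind == "smooth":
                if blk.name not in X.columns:
                    raise KeyError(f"prediction data lacks column {blk.name!r}")
                design, out = blk.basis.transform(X[blk.name].to_numpy())
                D[:, blk.sl] = design @ blk.Z
                flags |= out
            else:
                if blk.name not in X.columns:
                    raise KeyError(f"prediction data lacks column {blk.name!r}")
                design = self._dummies(X[blk.name].to_numpy(), blk.levels)
                D[:, blk.sl] = design - blk.center
        return D, flags

    # ------------------------------------------------------------------
    # fitting

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
        y = np.asarray(y, dtype=float)
        used = self._required_columns()
        missing = [c for c in used if c not in X.columns]
        if missing:
            raise KeyError(f"data lacks model columns: {missing}")
        keep = ~(X[used].isna().any(axis=1).to_numpy() | ~np.isfinite(y))
        self.n_dropped_ = int((~keep).sum())
        Xk, yk = X.loc[keep, used].reset_index(drop=True), y[keep]
        n = len(Xk)
        D, blocks, penalties = self._assemble_training(Xk)
        p = D.shape[1]
        if n <= p:
            raise GamFitError(f"need more rows ({n}) than coefficients ({p})")
        self.blocks_ = blocks
        self.n_coef_ = p
        if np.linalg.matrix_rank(D) < p:
            self._diagnose_rank(D, blocks)
            raise GamFitError("design matrix is rank deficient after constraints")
        DtD = D.T @ D
        Dty = D.T @ yk

        smooth_names = [b.name for b in blocks if b.kind == "smooth"]
        if self.lam is not None:
            lam = (
                {v: float(self.lam) for v in smooth_names}
                if np.isscalar(self.lam)
                else {v: float(self.lam[v]) for v in smooth_names}
            )
        elif smooth_names:
            lam = self._select_lambda(D, yk, DtD, Dty, penalties, smooth_names)
        else:
            lam = {}
        self.lambda_ = lam

        A = self._penalized_gram(DtD, penalties, smooth_names, lam)
        try:
            beta = np.linalg.solve(A, Dty)
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            self._diagnose_rank(D, blocks)
            raise GamFitError("penalized normal equations are singular")
        resid = yk - D @ beta
        F = Ainv @ DtD
        edf = float(np.trace(F))
        rss = float(resid @ resid)
        self.coef_ = beta
        self.edf_ = edf
        self.edf_per_term_ = {
            b.name: float(np.sum(np.diag(F)[b.sl])) for b in blocks if b.kind == "smooth"
        }
        self.sigma2_ = rss / max(n - edf, 1.0)
        self.cov_ = self.sigma2_ * Ainv
        self.rss_ = rss
        self.gcv_ = n * rss / (n - edf) ** 2
        self.fitted_values_ = D @ beta
        self.n_obs_ = n
        self._train_index = X.index[keep]
        return self

    @staticmethod
    def _penalized_gram(DtD, penalties, smooth_names, lam):
        A = DtD.copy()
        for (sl, P), name in zip(penalties, smooth_names):
            A[sl, sl] += lam[name] * P
        return A

    def _criterion(self, logl, D, y, DtD, Dty, penalties, smooth_names):
        lam = {v: 10.0**l for v, l in zip(smooth_names, logl)}
        A = self._penalized_gram(DtD, penalties, smooth_names, lam)
        try:
            beta = np.linalg.solve(A, Dty)
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.inf
        resid = y - D @ beta
        rss = float(resid @ resid)
        n = len(y)
        if self.method == "reml":
            # profiled Gaussian restricted likelihood (up to constants)
            pen = sum(
                lam[name] * float(beta[sl] @ P @ beta[sl])
                for (sl, P), name in zip(penalties, smooth_names)
            )
            null_dim = D.shape[1] - sum(
                np.linalg.matrix_rank(P) for (_, P) in penalties
            )
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            logdetS = 0.0
            for (sl, P), name in zip(penalties, smooth_names):
                ev = np.linalg.eigvalsh(P)
                pos = ev[ev > 1e-10 * ev.max()]
                logdetS += len(pos) * np.log(lam[name]) + float(np.sum(np.log(pos)))
            return (n - null_dim) * np.log(rss + pen) + logdetA - logdetS
        edf = float(np.trace(Ainv @ DtD))
        if edf >= n:
            return np.inf
        # tiny edf tie-break keeps the smoother fit when RSS is flat in lambda
        return n * rss / (n - edf) ** 2 + 1e-12 * edf

    def _select_lambda(self, D, y, DtD, Dty, penalties, smooth_names):
        lo, hi, num = self.lam_grid
        grid = np.linspace(hi, lo, int(num))  # descending: ties prefer smoother
        logl = np.full(len(smooth_names), 1.0)
        for _ in range(2):
            for j in range(len(smooth_names)):
                scores = []
                for g in grid:
                    trial = logl.copy()
                    trial[j] = g
                    scores.append(
                        self._criterion(trial, D, y, DtD, Dty, penalties, smooth_names)
                    )
                logl[j] = grid[int(np.argmin(scores))]
        if self.polish:
            from scipy.optimize import minimize

            res = minimize(
                self._criterion,
                logl,
                args=(D, y, DtD, Dty, penalties, smooth_names),
                method="Nelder-Mead",
                options={"xatol": 0.05, "fatol": 1e-10, "maxiter": 200},
            )
            if np.isfinite(res.fun):
                logl = res.x
        return {v: 10.0**l for v, l in zip(smooth_names, logl)}

    def _diagnose_rank(self, D, blocks):
        for blk in blocks:
            sub = D[:, blk.sl]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise GamFitError(f"design block for term {blk.name!r} is rank deficient")

    # ------------------------------------------------------------------
    # prediction

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D, _ = self._design(X)
        return D @ self.coef_

    def predict_with_se(self, X: pd.DataFrame):
        """Predictions, standard errors, and extrapolation flags."""
        D, flags = self._design(X)
        pred = D @ self.coef_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, self.cov_, D), 0.0))
        return pred, se, flags

    def prediction_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        pred, se, flags = self.predict_with_se(X)
        return pd.DataFrame(
            {"prediction": pred, "se": se, "extrapolated": flags}, index=X.index
        )

    def term_contributions(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-term additive contributions; they sum to the prediction."""
        D, _ = self._design(X)
        out = {}
        for blk in self.blocks_:
            out[blk.name] = D[:, blk.sl] @ self.coef_[blk.sl]
        return pd.DataFrame(out, index=X.index)

    def contrast_se(self, C: np.ndarray) -> np.ndarray:
        """SE of arbitrary linear functionals ``C @ coef_``."""
        C = np.atleast_2d(np.asarray(C, dtype=float))
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, self.cov_, C), 0.0))

    def difference_se(self, Xa: pd.DataFrame, Xb: pd.DataFrame) -> np.ndarray:
        """SE of the per-row prediction difference ``predict(Xa) - predict(Xb)``.

        The two designs share coefficients, so the contrast is the row
        difference of the design matrices; this is the model uncertainty
        of an emission-impact series at identical meteorology.
        """
        Da, _ = self._design(Xa)
        Db, _ = self._design(Xb)
        return self.contrast_se(Da - Db)

    def mean_difference_se(self, Xa: pd.DataFrame, Xb: pd.DataFrame) -> float:
        """SE of the mean prediction difference over the supplied rows."""
        Da, _ = self._design(Xa)
        Db, _ = self._design(Xb)
        c = (Da - Db).mean(axis=0)
        return float(self.contrast_se(c)[0])

    # ------------------------------------------------------------------
    # portability

    def to_dict(self) -> dict:
        blocks = []
        for b in self.blocks_:
            blocks.append(
                {
                    "name": b.name,
                    "kind": b.kind,
                    "start": b.sl.start,
                    "stop": b.sl.stop,
                    "basis": b.basis.to_dict() if b.basis is not None else None,
                    "levels": (
                        [lv.item() if hasattr(lv, "item") else lv for lv in b.levels]
                        if b.levels is not None
                        else None
                    ),
                    "center": b.center.tolist() if b.center is not None else None,
                    "Z": b.Z.tolist() if b.Z is not None else None,
                }
            )
        return {
            "coef": self.coef_.tolist(),
            "cov": self.cov_.tolist(),
            "lambda": {k: float(v) for k, v in self.lambda_.items()},
            "sigma2": float(self.sigma2_),
            "edf": float(self.edf_),
            "edf_per_term": self.edf_per_term_,
            "n_obs": self.n_obs_,
            "blocks": blocks,
            "params": {
                "smooth_terms": self._smooth_spec(),
                "categorical_terms": list(self.categorical_terms or []),
                "method": self.method,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineGAM":
        self = cls(
            smooth_terms=d["params"]["smooth_terms"],
            categorical_terms=d["params"]["categorical_terms"],
            method=d["params"]["method"],
        )
        self.coef_ = np.asarray(d["coef"], dtype=float)
        self.cov_ = np.asarray(d["cov"], dtype=float)
        self.lambda_ = d["lambda"]
        self.sigma2_ = d["sigma2"]
        self.edf_ = d["edf"]
        self.edf_per_term_ = d["edf_per_term"]
        self.n_obs_ = d["n_obs"]
        blocks = []
        for b in d["blocks"]:
            blocks.append(
                _TermBlock(
                    name=b["name"],
                    kind=b["kind"],
                    sl=slice(b["start"], b["stop"]),
                    basis=CubicRegressionSpline.from_dict(b["basis"]) if b["basis"] else None,
                    levels=b["levels"],
                    center=np.asarray(b["center"]) if b["center"] is not None else None,
                    Z=np.asarray(b["Z"]) if b.get("Z") is not None else None,
                )
            )
        self.blocks_ = blocks
        self.n_coef_ = len(self.coef_)
        return self


def add_calendar_columns(df: pd.DataFrame, date_col: str | None = None) -> pd.DataFrame:
    """Attach ``day_of_week`` (0=Monday) and ``month`` columns from dates."""
    out = df.copy()
    dates = pd.DatetimeIndex(out[date_col]) if date_col else pd.DatetimeIndex(out.index)
    out["day_of_week"] = dates.dayofweek
    out["month"] = dates.month
    return out
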