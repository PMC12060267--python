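"""Uncertainty-weighted positive matrix factorization for receptor modelling.

Decomposes a speciated concentration matrix X (day × species) with paired
measurement uncertainties S into nonnegative daily source contributions G
and source profiles F, minimizing the uncertainty-scaled objective

    Q(G, F) = sum_ij ((X_ij - (G F)_ij) / S_ij)^2

by monotone multiplicative updates from several random nonnegative starts.
Dispersion normalization multiplies each day by a ventilation-based
multiplier before factorization so that recovered factors track emission
strength rather than atmospheric mixing, and is inverted on the
contributions afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import SpeciationDataset

_EPS = 1e-12


class NormalizationError(ValueError):
    pass


@dataclass
class DispersionNormalizer:
    """Daily dilution multipliers m_i = V_i / mean(V).

    ``V`` is a ventilation proxy per day (mixing-depth proxy × wind
    speed, or user supplied). By construction mean(m) = 1, so the
    normalized data keep the original overall scale.
    """

    ventilation: pd.Series

    def __post_init__(self):
        v = self.ventilation.astype(float)
        if (v <= 0).any() or not np.isfinite(v).all():
            raise NormalizationError("ventilation proxy must be finite and positive")
        self.multipliers = v / v.mean()

    @classmethod
    def from_met(cls, met: pd.DataFrame, mixing_proxy: pd.Series | None = None) -> "DispersionNormalizer":
        """Build from meteorology: V = mixing proxy × wind speed.

        Without an explicit mixing-depth proxy, a temperature-driven
        stand-in (warmer days mix deeper) keeps the multiplier positive.
        """
        ws = met["wind_speed"].clip(lower=0.1)
        if mixing_proxy is None:
            t = met["temperature"]
            mixing_proxy = 1.0 + (t - t.min()) / max(t.max() - t.min(), _EPS)
        return cls(ventilation=mixing_proxy * ws)

    def normalize(self, dataset: SpeciationDataset) -> SpeciationDataset:
        m = self.multipliers.reindex(dataset.X.index)
        if m.isna().any():
            raise NormalizationError("normalizer dates do not cover dataset dates")
        return SpeciationDataset(
            X=dataset.X.mul(m, axis=0),
            S=dataset.S.mul(m, axis=0),
            detection_limits=dataset.detection_limits,
        )

    def denormalize_contributions(self, G: pd.DataFrame) -> pd.DataFrame:
        m = self.multipliers.reindex(G.index)
        return G.div(m, axis=0)


def compute_q(X: np.ndarray, S: np.ndarray, G: np.ndarray, F: np.ndarray):
    """Objective value and the matrix of uncertainty-scaled residuals."""
    X, S = np.asarray(X, float), np.asarray(S, float)
    model = np.asarray(G, float) @ np.asarray(F, float)
    if model.shape != X.shape or S.shape != X.shape:
        raise ValueError("shape mismatch between data, uncertainties and model")
    residuals = (X - model) / S
    return float(np.sum(residuals**2)), residuals


@dataclass
class FactorModel:
    """Fitted factorization: X ≈ G·F with profiles normalized to sum 1."""

    G: pd.DataFrame          # day × factor contributions, µg/m³
    F: pd.DataFrame          # factor × species profiles, rows sum to 1
    Q: float
    convergence: dict = field(default_factory=dict)

    @property
    def reconstruction(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.G.to_numpy() @ self.F.to_numpy(),
            index=self.G.index,
            columns=self.F.columns,
        )


class WeightedPMF(BaseEstimator, TransformerMixin):
    """Positive matrix factorization weighted by measurement uncertainty.

    Parameters
    ----------
    n_factors : int
        Number of source factors to extract (a modelling choice made per
        site; e.g. nine or ten factors in typical urban applications).
    n_random_starts : int
        Independent nonnegative random initializations; the solution
        with the lowest Q is kept.
    max_iterations : int
        Cap on multiplicative-update iterations per start.
    tol : float
        Convergence: relative Q change below ``tol`` sustained over 10
        consecutive iterations.
    seed : int
        Seed for the random starts.

    Attributes
    ----------
    model_ : FactorModel   best factorization found
    q_history_ : list      Q per iteration for the winning start
    """

    def __init__(self, n_factors=3, n_random_starts=10, max_iterations=5000, tol=1e-8, seed=0):
        self.n_factors = n_factors
        self.n_random_starts = n_random_starts
        self.max_iterations = max_iterations
        self.tol = tol
        self.seed = seed

    def fit(self, dataset: SpeciationDataset, y=None):
        X = dataset.X.to_numpy(dtype=float)
        S = dataset.S.to_numpy(dtype=float)
        if not (np.isfinite(X).all() and np.isfinite(S).all()):
            raise ValueError("X and S must be finite")
        if (S <= 0).any():
            raise ValueError("uncertainties S must be strictly positive")
        n, m = X.shape
        if not 1 <= self.n_factors <= min(n, m):
            raise ValueError(f"n_factors must lie in [1, {min(n, m)}]")
        if self.n_random_starts < 1:
            raise ValueError("n_random_starts must be >= 1")
        W = 1.0 / S**2
        WX = W * np.maximum(X, 0.0)
        rng = np.random.default_rng(self.seed)
        best = None
        for start in range(self.n_random_starts):
            G, F, q_hist, converged = self._run_start(X, W, WX, rng)
            if best is None or q_hist[-1] < best[2][-1]:
                best = (G, F, q_hist, converged, start)
        G, F, q_hist, converged, start = best
        if not converged:
            warnings.warn("PMF did not converge within max_iterations; best iterate returned")
        # move profile scale into G so rows of F sum to 1
        scale = F.sum(axis=1)
        scale[scale < _EPS] = _EPS
        F = F / scale[:, None]
        G = G * scale[None, :]
        factors = [f"factor_{k+1}" for k in range(self.n_factors)]
        self.model_ = FactorModel(
            G=pd.DataFrame(G, index=dataset.X.index, columns=factors),
            F=pd.DataFrame(F, index=factors, columns=dataset.X.columns),
            Q=q_hist[-1],
            convergence={
                "iterations": len(q_hist) - 1,
                "converged": converged,
                "winning_start": start,
                "q_history": q_hist,
            },
        )
        self.q_history_ = q_hist
        return self

    def _run_start(self, X, W, WX, rng):
        n, m = X.shape
        k = self.n_factors
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        G = rng.uniform(0.1, 1.0, size=(n, k)) * scale
        F = rng.uniform(0.1, 1.0, size=(k, m)) * scale
        model = G @ F
        q = float(np.sum(W * (X - model) ** 2))
        q_hist = [q]
        stable = 0
        converged = False
        for _ in range(self.max_iterations):
            # weighted multiplicative updates (monotone for this objective)
            G *= (WX @ F.T) / ((W * (G @ F)) @ F.T + _EPS)
            F *= (G.T @ WX) / (G.T @ (W * (G @ F)) + _EPS)
            model = G @ F
            q_new = float(np.sum(W * (X - model) ** 2))
            q_hist.append(q_new)
            rel = abs(q - q_new) / max(q, _EPS)
            stable = stable + 1 if rel < self.tol else 0
            q = q_new
            if stable >= 10:
                converged = True
                break
        return G, F, q_hist, converged

    def fit_transform(self, dataset: SpeciationDataset, y=None) -> pd.DataFrame:
        return self.fit(dataset).model_.G

    def transform(self, dataset: SpeciationDataset) -> pd.DataFrame:
        """Contributions for new days at the fitted profiles (G-only solve)."""
        F = self.model_.F.to_numpy()
        X = dataset.X.reindex(columns=self.model_.F.columns).to_numpy(dtype=float)
        S = dataset.S.reindex(columns=self.model_.F.columns).to_numpy(dtype=float)
        W = 1.0 / S**2
        WX = W * np.maximum(X, 0.0)
        rng = np.random.default_rng(self.seed)
        G = rng.uniform(0.1, 1.0, size=(X.shape[0], self.n_factors)) * np.sqrt(
            max(X.mean(), _EPS) / self.n_factors
        )
        for _ in range(self.max_iterations):
            G_new = G * (WX @ F.T) / ((W * (G @ F)) @ F.T + _EPS)
            if np.max(np.abs(G_new - G)) < self.tol * (np.max(G) + _EPS):
                G = G_new
                break
            G = G_new
        return pd.DataFrame(G, index=dataset.X.index, columns=self.model_.F.index)


def match_factors(F_model: pd.DataFrame, F_reference: pd.DataFrame):
    """One-to-one factor assignment maximizing total cosine similarity.

    PMF factor order is arbitrary; this solves the optimal bipartite
    assignment between recovered and reference profiles and returns
    ``(mapping, similarities)`` where ``mapping[model_factor] =
    reference_factor``.
    """
    A = F_model.to_numpy(dtype=float)
    B = F_reference.to_numpy(dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("factor counts differ between model and reference")
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    sim = An @ Bn.T
    rows, cols = linear_sum_assignment(-sim)
    mapping = {F_model.index[r]: F_reference.index[c] for r, c in zip(rows, cols)}
    sims = {F_model.index[r]: float(sim[r, c]) for r, c in zip(rows, cols)}
    return mapping, sims
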