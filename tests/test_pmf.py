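"""Weighted factorization: objective, monotonicity, recovery, matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aq_accountant.pmf import (
    DispersionNormalizer,
    NormalizationError,
    WeightedPMF,
    compute_q,
    match_factors,
)
from aq_accountant.synth import SpeciationDataset, three_factor_speciation


def _dataset(X, S=None):
    X = pd.DataFrame(X)
    X.index = pd.date_range("2005-01-01", periods=len(X), freq="D")
    S = pd.DataFrame(S, index=X.index, columns=X.columns) if S is not None else X * 0 + 1.0
    return SpeciationDataset(X=X, S=S, detection_limits=pd.Series(0.0, index=X.columns))


@pytest.fixture(scope="module")
def benchmark():
    return three_factor_speciation(n_days=400, n_species=12, seed=21)


class TestDispersionNormalizer:
    def test_unit_multipliers_identity(self, benchmark):
        ds, _, _ = benchmark
        norm = DispersionNormalizer(ventilation=pd.Series(1.0, index=ds.X.index))
        out = norm.normalize(ds)
        pd.testing.assert_frame_equal(out.X, ds.X)

    def test_day_with_double_multiplier(self):
        ds = _dataset(np.ones((4, 2)))
        v = pd.Series([1.0, 2.0, 0.5, 0.5], index=ds.X.index)
        norm = DispersionNormalizer(ventilation=v)
        out = norm.normalize(ds)
        m = (v / v.mean()).iloc[1]
        assert np.allclose(out.X.iloc[1], m)
        assert np.allclose(out.S.iloc[1], m)

    def test_round_trip(self, benchmark):
        ds, _, _ = benchmark
        rng = np.random.default_rng(0)
        v = pd.Series(rng.uniform(0.5, 3.0, len(ds.X)), index=ds.X.index)
        norm = DispersionNormalizer(ventilation=v)
        out = norm.normalize(ds)
        back = out.X.div(norm.multipliers, axis=0)
        rel = np.abs(back.to_numpy() - ds.X.to_numpy()) / np.maximum(np.abs(ds.X.to_numpy()), 1e-300)
        assert rel.max() < 1e-12

    def test_mean_multiplier_is_one(self):
        v = pd.Series([0.2, 5.0, 1.0, 2.0])
        assert DispersionNormalizer(ventilation=v).multipliers.mean() == pytest.approx(1.0)

    def test_nonpositive_ventilation_rejected(self):
        with pytest.raises(NormalizationError):
            DispersionNormalizer(ventilation=pd.Series([1.0, 0.0, 2.0]))


class TestComputeQ:
    def test_exact_model_gives_zero(self):
        rng = np.random.default_rng(1)
        G = rng.uniform(0, 1, (10, 2))
        F = rng.uniform(0, 1, (2, 5))
        q, resid = compute_q(G @ F, np.ones((10, 5)), G, F)
        assert q == 0.0
        assert resid.shape == (10, 5)

    def test_single_cell_off_by_two_sigma(self):
        G = np.ones((3, 1))
        F = np.ones((1, 2))
        X = G @ F
        S = np.full_like(X, 0.5)
        X[1, 1] += 2 * S[1, 1]
        q, _ = compute_q(X, S, G, F)
        assert q == pytest.approx(4.0)

    def test_matches_naive_double_loop(self, rng):
        X = rng.uniform(0, 5, (6, 4))
        S = rng.uniform(0.1, 1, (6, 4))
        G = rng.uniform(0, 2, (6, 2))
        F = rng.uniform(0, 1, (2, 4))
        q, _ = compute_q(X, S, G, F)
        naive = sum(
            ((X[i, j] - (G @ F)[i, j]) / S[i, j]) ** 2
            for i in range(6)
            for j in range(4)
        )
        assert q == pytest.approx(naive, rel=1e-12)


class TestFit:
    def test_rank_one_exact_factorization(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(1, 5, 50)
        f = rng.uniform(0.1, 1, 6)
        X = np.outer(g, f)
        ds = _dataset(X, np.full_like(X, 0.3))
        pmf = WeightedPMF(n_factors=1, n_random_starts=3, seed=0).fit(ds)
        assert pmf.model_.Q < 1e-6 * X.size
        recon = pmf.model_.reconstruction.to_numpy()
        assert np.max(np.abs(recon - X) / X) < 1e-4

    def test_q_monotone_nonincreasing(self, benchmark):
        ds, _, _ = benchmark
        pmf = WeightedPMF(n_factors=3, n_random_starts=2, max_iterations=400, seed=4).fit(ds)
        q = np.asarray(pmf.q_history_)
        assert np.all(np.diff(q) <= q[:-1] * 1e-9 + 1e-9)

    def test_profiles_row_normalized_and_nonnegative(self, benchmark):
        ds, _, _ = benchmark
        pmf = WeightedPMF(n_factors=3, n_random_starts=2, max_iterations=400, seed=4).fit(ds)
        F, G = pmf.model_.F, pmf.model_.G
        assert np.allclose(F.sum(axis=1), 1.0, atol=1e-9)
        assert (F.to_numpy() >= 0).all() and (G.to_numpy() >= 0).all()

    def test_species_permutation_equivariance(self, benchmark):
        ds, _, _ = benchmark
        perm = [3, 1, 0, 2, 5, 4, 6, 7, 11, 9, 10, 8]
        cols = [ds.X.columns[i] for i in perm]
        ds_p = SpeciationDataset(
            X=ds.X[cols], S=ds.S[cols], detection_limits=ds.detection_limits[cols]
        )
        a = WeightedPMF(n_factors=2, n_random_starts=2, max_iterations=3000, seed=5).fit(ds)
        b = WeightedPMF(n_factors=2, n_random_starts=2, max_iterations=3000, seed=5).fit(ds_p)
        # random starts are positional and factor labels arbitrary, so
        # equivariance holds at the optimum up to factor permutation
        assert a.model_.Q == pytest.approx(b.model_.Q, rel=1e-5)
        mapping, sims = match_factors(a.model_.F, b.model_.F[cols].set_axis(a.model_.F.columns, axis=1))
        aligned = b.model_.F.rename(index={v: k for k, v in mapping.items()}).loc[a.model_.F.index]
        pd.testing.assert_frame_equal(
            a.model_.F[cols], aligned, check_exact=False, atol=1e-3
        )

    def test_doubling_s_quarters_q(self, benchmark):
        ds, _, _ = benchmark
        pmf = WeightedPMF(n_factors=3, n_random_starts=1, max_iterations=200, seed=6).fit(ds)
        G, F = pmf.model_.G.to_numpy(), pmf.model_.F.to_numpy()
        q1, _ = compute_q(ds.X.to_numpy(), ds.S.to_numpy(), G, F)
        q2, _ = compute_q(ds.X.to_numpy(), 2 * ds.S.to_numpy(), G, F)
        assert q2 == pytest.approx(q1 / 4, rel=1e-12)

    def test_modeled_total_invariant_to_normalization(self, benchmark):
        """Moving profile scale into G leaves the modeled X unchanged."""
        ds, _, _ = benchmark
        pmf = WeightedPMF(n_factors=3, n_random_starts=1, max_iterations=200, seed=6).fit(ds)
        q_norm, _ = compute_q(
            ds.X.to_numpy(), ds.S.to_numpy(),
            pmf.model_.G.to_numpy(), pmf.model_.F.to_numpy(),
        )
        assert q_norm == pytest.approx(pmf.model_.Q, rel=1e-9)

    def test_noise_free_contributions_recovered(self):
        """Zeros in both profiles and contributions pin the factorization."""
        _, g_true, _ = three_factor_speciation(
            n_days=400, n_species=12, proportional_noise=0.0, detection_limit=0.0, seed=31
        )
        rng = np.random.default_rng(8)
        g_true = g_true.copy()
        for j in range(3):  # source-absent days (e.g. holidays, stagnation-free)
            off = rng.choice(len(g_true), size=25, replace=False)
            g_true.iloc[off, j] = 0.0
        f_true = np.zeros((3, 12))
        for j in range(3):  # each factor owns a disjoint species block
            f_true[j, 4 * j : 4 * (j + 1)] = rng.uniform(0.2, 1.0, 4)
        f_true /= f_true.sum(axis=1, keepdims=True)
        f_true = pd.DataFrame(f_true, index=g_true.columns,
                              columns=[f"sp{i}" for i in range(12)])
        X = g_true.to_numpy() @ f_true.to_numpy()
        ds = _dataset(X, np.full_like(X, 0.05))
        ds.X.index = g_true.index
        ds.S.index = g_true.index
        pmf = WeightedPMF(n_factors=3, n_random_starts=5, seed=7).fit(ds)
        mapping, sims = match_factors(pmf.model_.F.set_axis(f_true.columns, axis=1), f_true)
        g = pmf.model_.G.rename(columns=mapping)
        for f in f_true.index:
            assert np.corrcoef(g[f], g_true[f])[0, 1] >= 0.99

    def test_nonpositive_uncertainty_rejected(self):
        ds = _dataset(np.ones((5, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            WeightedPMF(n_factors=1).fit(ds)

    def test_bad_factor_count_rejected(self, benchmark):
        ds, _, _ = benchmark
        with pytest.raises(ValueError):
            WeightedPMF(n_factors=0).fit(ds)


class TestMatchFactors:
    def test_self_match_is_identity(self, benchmark):
        _, _, F = benchmark
        mapping, sims = match_factors(F, F)
        assert mapping == {f: f for f in F.index}
        assert all(s == pytest.approx(1.0) for s in sims.values())

    def test_reversed_order_recovered(self, benchmark):
        _, _, F = benchmark
        mapping, _ = match_factors(F, F.iloc[::-1])
        assert mapping == {f: f for f in F.index}

    def test_agrees_with_brute_force(self, rng):
        F = pd.DataFrame(rng.uniform(0, 1, (3, 8)), index=list("abc"))
        noisy = F + rng.normal(0, 0.05, F.shape)
        ref = noisy.iloc[[2, 0, 1]].set_axis(list("xyz"))
        mapping, sims = match_factors(F, ref)

        An = F.to_numpy() / np.linalg.norm(F.to_numpy(), axis=1, keepdims=True)
        Bn = ref.to_numpy() / np.linalg.norm(ref.to_numpy(), axis=1, keepdims=True)
        simmat = An @ Bn.T
        best = max(
            itertools.permutations(range(3)),
            key=lambda p: sum(simmat[i, p[i]] for i in range(3)),
        )
        expected = {F.index[i]: ref.index[best[i]] for i in range(3)}
        assert mapping == expected

    def test_count_mismatch_rejected(self, benchmark):
        _, _, F = benchmark
        with pytest.raises(ValueError):
            match_factors(F, F.iloc[:2])
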