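"""Each full conditional is checked against an independent dense-matrix or
distributional oracle on a fixed 3-genotype, 2-environment instance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bfamet as bf
from bfamet import gibbs as gb
from bfamet.met_data import build_design_matrices
from bfamet.model import ModelState, PriorSpec, genetic_component

N_DRAWS = 100_000


@pytest.fixture(scope="module")
def instance():
    design = bf.SimulationDesign(
        m=3, p=2, q=2, group_sizes=(1, 1, 1), residual_variances=(0.5, 2.0)
    )
    data, _ = bf.simulate_met(design, seed=3)
    dm = build_design_matrices(data)
    rng = np.random.default_rng(42)
    alphas, _ = np.linalg.qr(rng.standard_normal((2, 2)))
    state = ModelState(
        beta=rng.standard_normal(4),
        lambdas=np.array([1.7, 0.6]),
        alphas=alphas,
        f=rng.standard_normal((3, 2)),
        delta=0.3 * rng.standard_normal(6),
        psi=np.array([0.8, 0.5]),
        sigma_e2=np.array([0.5, 2.0]),
    )
    return data, dm, state


def draw_many(fn, n=N_DRAWS, seed=1):
    rng = np.random.default_rng(seed)
    return np.array([fn(rng) for _ in range(n)])


def dense_pieces(data, dm, state):
    X1 = dm.X1.toarray()
    X2 = dm.X2.toarray()
    Z = dm.Z.toarray()
    Zf = dm.Zf.toarray()
    Rinv = np.diag(1.0 / state.sigma_e2[dm.env_index])
    return X1, X2, Z, Zf, Rinv


class TestSampleBeta:
    def test_moments_match_dense_gaussian(self, instance):
        data, dm, state = instance
        y = data.y
        X1, _, _, _, Rinv = dense_pieces(data, dm, state)
        a0 = y - genetic_component(state, dm) - state.delta[dm.ge_index]
        M = X1.T @ Rinv @ X1
        mean = np.linalg.solve(M, X1.T @ Rinv @ a0)
        cov = np.linalg.inv(M)
        draws = draw_many(lambda rng: gb.sample_beta(state, dm, y, PriorSpec(), rng))
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * se)
        assert np.abs(np.cov(draws.T) - cov).max() < 0.05 * np.abs(cov).max()

    def test_cell_mean_identity_homoscedastic(self, instance):
        """With equal residual variances and zeroed random effects the
        conditional mean is the vector of cell means."""
        data, dm, state = instance
        st = state.copy()
        st.sigma_e2 = np.array([1.5, 1.5])
        st.f = np.zeros_like(st.f)
        st.delta = np.zeros_like(st.delta)
        draws = draw_many(
            lambda rng: gb.sample_beta(st, dm, data.y, PriorSpec(), rng), 20_000
        )
        counts = np.bincount(dm.cell_index)
        cell_means = np.bincount(dm.cell_index, weights=data.y) / counts
        se = np.sqrt(1.5 / counts / 20_000)
        assert np.all(np.abs(draws.mean(0) - cell_means) < 4 * se)


class TestSampleF:
    def test_moments_match_dense_gaussian(self, instance):
        data, dm, state = instance
        y = data.y
        X1, X2, Z, Zf, Rinv = dense_pieces(data, dm, state)
        m, k = state.f.shape
        A4 = np.hstack([
            state.lambdas[kk] * np.diag(X2 @ state.alphas[:, kk]) @ Zf
            for kk in range(k)
        ])
        a5 = y - state.beta[dm.cell_index] - state.delta[dm.ge_index]
        P = np.eye(m * k) + A4.T @ Rinv @ A4
        mean = np.linalg.solve(P, A4.T @ Rinv @ a5)
        cov = np.linalg.inv(P)
        # A4 stacks factor-major blocks: draw matrix -> column-major flatten
        draws = draw_many(
            lambda rng: gb.sample_f(state, dm, y, rng).T.ravel()
        )
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * se)
        assert np.abs(np.cov(draws.T) - cov).max() < 0.05 * np.abs(cov).max()

    def test_prior_when_no_loading_information(self, instance):
        data, dm, state = instance
        st = state.copy()
        st.lambdas = np.zeros(2)
        draws = draw_many(
            lambda rng: gb.sample_f(st, dm, data.y, rng).ravel(), 20_000
        )
        assert np.all(np.abs(draws.mean(0)) < 4 / np.sqrt(20_000))
        assert np.abs(draws.var(0) - 1.0).max() < 0.05


class TestSampleDelta:
    def test_moments_match_dense_gaussian(self, instance):
        data, dm, state = instance
        y = data.y
        X1, X2, Z, Zf, Rinv = dense_pieces(data, dm, state)
        a7 = y - state.beta[dm.cell_index] - genetic_component(state, dm)
        Minv = np.linalg.inv(np.kron(np.eye(3), np.diag(state.psi)))
        P = Z.T @ Rinv @ Z + Minv
        mean = np.linalg.solve(P, Z.T @ Rinv @ a7)
        cov = np.linalg.inv(P)
        draws = draw_many(lambda rng: gb.sample_delta(state, dm, y, rng))
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * se)
        assert np.abs(np.cov(draws.T) - cov).max() < 0.05 * np.abs(cov).max()

    def test_tight_prior_shrinks_to_zero(self, instance):
        data, dm, state = instance
        st = state.copy()
        st.psi = np.full(2, 1e-12)
        draws = draw_many(lambda rng: gb.sample_delta(st, dm, data.y, rng), 5_000)
        assert np.abs(draws.mean(0)).max() < 1e-6

    def test_scalar_conjugacy_single_cell(self):
        """One genotype, one environment, two replicates, R=I, psi=1:
        the conditional is N(2 rbar / 3, 1/3)."""
        data = bf.METDataset(pd.DataFrame({
            "genotype": ["G1", "G1"], "environment": ["E1", "E1"],
            "block": ["B1", "B2"], "value": [1.2, 0.4],
        }))
        dm = build_design_matrices(data)
        state = ModelState(
            beta=np.zeros(2), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((1, 1)), delta=np.zeros(1), psi=np.ones(1),
            sigma_e2=np.ones(1),
        )
        rbar = data.y.mean()
        draws = draw_many(lambda rng: gb.sample_delta(state, dm, data.y, rng)[0])
        assert draws.mean() == pytest.approx(2 * rbar / 3, abs=4 * np.sqrt(1 / 3 / N_DRAWS))
        assert draws.var() == pytest.approx(1 / 3, rel=0.05)

    def test_zero_psi_outside_full_rank_errors(self, instance):
        data, dm, state = instance
        st = state.copy()
        st.psi = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            gb.sample_delta(st, dm, data.y, np.random.default_rng(0))


class TestSampleLambda:
    def test_moments_match_truncated_normal_oracle(self, instance):
        data, dm, state = instance
        y = data.y
        w = 1.0 / state.sigma_e2[dm.env_index]
        comp = state.alphas[dm.env_index, 0] * state.f[dm.gen_index, 0]
        a1 = (
            y - state.beta[dm.cell_index]
            - (genetic_component(state, dm) - state.lambdas[0] * comp)
            - state.delta[dm.ge_index]
        )
        prec = np.sum(w * comp**2)
        mean = np.sum(w * comp * a1) / prec
        sd = 1.0 / np.sqrt(prec)
        a = (state.lambdas[1] - mean) / sd
        draws = draw_many(lambda rng: gb.sample_lambda(0, state, dm, y, PriorSpec(), rng))
        oracle = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
        assert draws.mean() == pytest.approx(
            oracle.mean(), abs=4 * oracle.std() / np.sqrt(len(draws))
        )
        assert draws.var() == pytest.approx(oracle.var(), rel=0.05)
        assert draws.min() >= state.lambdas[1]

    def test_ordering_bounds_respected(self, instance):
        data, dm, state = instance
        draws = draw_many(
            lambda rng: gb.sample_lambda(1, state, dm, data.y, PriorSpec(), rng),
            5_000,
        )
        assert np.all(draws >= 0.0)
        assert np.all(draws <= state.lambdas[0])

    def test_null_factor_falls_back_to_prior(self, instance):
        data, dm, state = instance
        st = state.copy()
        st.f = np.zeros_like(st.f)
        with pytest.warns(RuntimeWarning, match="numerically null"):
            val = gb.sample_lambda(1, st, dm, data.y, PriorSpec(), np.random.default_rng(0))
        assert 0.0 <= val <= st.lambdas[0]


class TestTruncatedNormalDraw:
    def test_inactive_truncation_matches_plain_normal(self):
        rng = np.random.default_rng(0)
        draws = np.array([
            gb._truncnorm_draw(rng, 0.0, 1.0, -50.0, 50.0) for _ in range(N_DRAWS)
        ])
        ks = stats.kstest(draws, "norm")
        assert ks.statistic < 0.01

    def test_bound_respected_far_from_mean(self):
        rng = np.random.default_rng(1)
        draws = np.array([
            gb._truncnorm_draw(rng, -10.0, 1.0, 0.0, np.inf) for _ in range(2_000)
        ])
        assert np.all(draws >= 0.0)

    def test_matches_rejection_sampling_oracle(self):
        mean, sd, lo, hi = 0.4, 1.3, -0.5, 2.0
        rng = np.random.default_rng(2)
        draws = np.array([
            gb._truncnorm_draw(rng, mean, sd, lo, hi) for _ in range(N_DRAWS)
        ])
        # rejection oracle: plain normals filtered to the interval
        rng2 = np.random.default_rng(3)
        raw = mean + sd * rng2.standard_normal(4 * N_DRAWS)
        oracle = raw[(raw >= lo) & (raw <= hi)]
        ks = stats.ks_2samp(draws, oracle)
        assert ks.pvalue > 0.01


class TestGramSchmidtComplement:
    def test_empty_constraint_spans_whole_space(self):
        Hk = gb.gram_schmidt_complement(np.zeros((4, 0)))
        np.testing.assert_allclose(Hk.T @ Hk, np.eye(4), atol=1e-12)

    def test_canonical_complement(self):
        e1 = np.eye(3)[:, :1]
        Hk = gb.gram_schmidt_complement(e1)
        assert Hk.shape == (3, 2)
        np.testing.assert_allclose(Hk.T @ e1, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_complement_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        Hs, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        Hk = gb.gram_schmidt_complement(Hs)
        assert Hk.shape == (8, 5)
        assert np.abs(Hs.T @ Hk).max() < 1e-10
        assert np.abs(Hk.T @ Hk - np.eye(5)).max() < 1e-10

    def test_rejects_non_orthonormal_input(self):
        with pytest.raises(ValueError, match="orthonormal"):
            gb.gram_schmidt_complement(2.0 * np.eye(3)[:, :2])


class TestSampleAlpha:
    def test_postconditions_norm_and_orthogonality(self, instance):
        data, dm, state = instance
        rng = np.random.default_rng(0)
        for _ in range(200):
            a2 = gb.sample_alpha(1, state, dm, data.y, rng)
            assert abs(np.linalg.norm(a2) - 1.0) < 1e-12
            assert abs(a2 @ state.alphas[:, 0]) < 1e-10

    def test_first_factor_unconstrained_reduces_to_normalized_gaussian(self, instance):
        data, dm, state = instance
        rng = np.random.default_rng(0)
        a1 = gb.sample_alpha(0, state, dm, data.y, rng)
        assert a1.shape == (2,)
        assert abs(np.linalg.norm(a1) - 1.0) < 1e-12

    def test_isotropic_conditional_uniform_on_great_circle(self):
        """With an isotropic zero-mean conditional the draw must be uniform
        on the sphere of the corrected subspace (the prior)."""
        design = bf.SimulationDesign(
            m=4, p=3, q=2, group_sizes=(1, 1, 2),
            residual_variances=(1.0, 1.0, 1.0),
        )
        data, _ = bf.simulate_met(design, seed=8)
        dm = build_design_matrices(data)
        alphas, _ = np.linalg.qr(np.random.default_rng(5).standard_normal((3, 2)))
        state = ModelState(
            beta=np.zeros(dm.n_cells), lambdas=np.array([1.0, 1.0]),
            alphas=alphas, f=np.ones((4, 2)), delta=np.zeros(12),
            psi=np.ones(3), sigma_e2=np.ones(3),
        )
        # y such that the factor-2 partial residual A3 vanishes -> zero mean;
        # equal f and variances make Delta' R^-1 Delta proportional to I
        comp = state.alphas[dm.env_index, 1] * state.f[dm.gen_index, 1]
        y = bf.predict_mean(state, dm) - state.lambdas[1] * comp
        basis = gb.gram_schmidt_complement(state.alphas[:, :1])
        rng = np.random.default_rng(6)
        angles = []
        for _ in range(30_000):
            a2 = gb.sample_alpha(1, state, dm, y, rng)
            z = basis.T @ a2  # 2D coordinates on the great circle
            angles.append(np.arctan2(z[1], z[0]))
        ks = stats.kstest(np.asarray(angles), stats.uniform(-np.pi, 2 * np.pi).cdf)
        assert ks.pvalue > 0.01

    def test_singular_conditional_falls_back_to_sphere(self, instance):
        data, dm, state = instance
        st = state.copy()
        st.f[:, 1] = 0.0
        with pytest.warns(RuntimeWarning, match="singular"):
            a2 = gb.sample_alpha(1, st, dm, data.y, np.random.default_rng(0))
        assert abs(np.linalg.norm(a2) - 1.0) < 1e-12


class TestVarianceConditionals:
    def test_psi_closed_form_moment(self):
        """delta all-ones of length 4, nu=1, S2=0 -> Scale-inv-chi2(5, 4/5)."""
        data = bf.METDataset(pd.DataFrame({
            "genotype": [f"G{i}" for i in range(1, 5) for _ in range(2)],
            "environment": "E1",
            "block": ["B1", "B2"] * 4,
            "value": np.arange(8.0),
        }))
        state = ModelState(
            beta=np.zeros(2), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((4, 1)), delta=np.ones(4), psi=np.ones(1),
            sigma_e2=np.ones(1),
        )
        draws = draw_many(
            lambda rng: gb.sample_psi(state, data, PriorSpec(), rng)[0]
        )
        # mean of Scale-inv-chi2(5, 4/5) = 5 * (4/5) / (5 - 2) = 4/3
        mc_se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 4 / 3) < 3 * mc_se

    def test_psi_zero_sum_of_squares_degenerates(self):
        data = bf.METDataset(pd.DataFrame({
            "genotype": ["G1", "G2"], "environment": "E1",
            "block": "B1", "value": [0.0, 1.0],
        }))
        state = ModelState(
            beta=np.zeros(1), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((2, 1)), delta=np.zeros(2), psi=np.ones(1),
            sigma_e2=np.ones(1),
        )
        draws = draw_many(
            lambda rng: gb.sample_psi(state, data, PriorSpec(), rng)[0], 1_000
        )
        assert np.all(draws == 0.0)

    def test_psi_matches_inverse_chi_squared_transform(self):
        data = bf.METDataset(pd.DataFrame({
            "genotype": [f"G{i}" for i in range(1, 7)], "environment": "E1",
            "block": "B1", "value": np.arange(6.0),
        }))
        delta = np.array([0.5, -1.0, 2.0, 0.3, -0.7, 1.2])
        state = ModelState(
            beta=np.zeros(1), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((6, 1)), delta=delta, psi=np.ones(1),
            sigma_e2=np.ones(1),
        )
        priors = PriorSpec(nu_k=2.0, S_k2=0.4)
        draws = draw_many(lambda rng: gb.sample_psi(state, data, priors, rng)[0])
        df = 6 + 2.0
        scale = (np.sum(delta**2) + 2.0 * 0.4) / df
        # Scale-inv-chi2(df, s2) == invgamma(df/2, scale = df s2 / 2)
        ks = stats.kstest(draws, stats.invgamma(df / 2, scale=df * scale / 2).cdf)
        assert ks.pvalue > 0.01

    def test_sigma_closed_form_moment(self):
        """Unit residuals at 4 observations -> Scale-inv-chi2(4, 1), mean 2."""
        data = bf.METDataset(pd.DataFrame({
            "genotype": ["G1", "G1", "G2", "G2"], "environment": "E1",
            "block": ["B1", "B2", "B1", "B2"], "value": np.ones(4),
        }))
        dm = build_design_matrices(data)
        state = ModelState(
            beta=np.zeros(2), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((2, 1)), delta=np.zeros(2), psi=np.ones(1),
            sigma_e2=np.ones(1),
        )  # theta == 0 so every residual is 1
        draws = draw_many(
            lambda rng: gb.sample_sigma_e(state, data, dm, PriorSpec(), rng)[0]
        )
        mc_se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 2.0) < 3 * mc_se

    def test_sigma_zero_residuals_concentrate_at_zero(self):
        data = bf.METDataset(pd.DataFrame({
            "genotype": ["G1", "G2"], "environment": "E1",
            "block": "B1", "value": [0.0, 0.0],
        }))
        dm = build_design_matrices(data)
        state = ModelState(
            beta=np.zeros(1), lambdas=np.zeros(1), alphas=np.ones((1, 1)),
            f=np.zeros((2, 1)), delta=np.zeros(2), psi=np.ones(1),
            sigma_e2=np.ones(1),
        )
        draws = draw_many(
            lambda rng: gb.sample_sigma_e(state, data, dm, PriorSpec(), rng)[0],
            1_000,
        )
        assert np.all(draws == 0.0)

    def test_sigma_matches_inverse_chi_squared_transform(self, instance):
        data, dm, state = instance
        resid = data.y - bf.predict_mean(state, dm)
        n1 = int(data.records_per_environment()[0])
        ss = float(np.sum(resid[dm.env_index == 0] ** 2))
        draws = draw_many(
            lambda rng: gb.sample_sigma_e(state, data, dm, PriorSpec(), rng)[0]
        )
        ks = stats.kstest(draws, stats.invgamma(n1 / 2, scale=ss / 2).cdf)
        assert ks.pvalue > 0.01
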