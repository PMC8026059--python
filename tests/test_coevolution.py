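import numpy as np
import pytest
from scipy.optimize import minimize

from coevotriplet.alphabet import N_STATES
from coevotriplet.coevolution import (DEFAULT_RHO, CovMatrix, PairScoreMap, apc_correct,
                                      assemble_feature_tensor, compute_cov, compute_plm,
                                      compute_pre, frobenius_score, plm_objective,
                                      tensor_to_blocks)
from coevotriplet.msa import Alignment, compute_frequencies, compute_weights_and_neff


def numeric_pre_minimizer(s: np.ndarray, rho: float) -> np.ndarray:
    """Independent oracle: generic L-BFGS minimization of
    G(Theta) = tr(S Theta) - log|Theta| + rho ||Theta||_F^2 over symmetric Theta."""
    n = s.shape[0]

    def fg(x):
        theta = x.reshape(n, n)
        theta = 0.5 * (theta + theta.T)
        try:
            chol = np.linalg.cholesky(theta)  # also certifies positive definiteness
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(x)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        grad = s - np.linalg.inv(theta) + 2 * rho * theta
        val = float(np.sum(s * theta) - logdet + rho * np.sum(theta * theta))
        return val, 0.5 * (grad + grad.T).ravel()

    def hessp(x, p):
        theta = x.reshape(n, n)
        theta = 0.5 * (theta + theta.T)
        pm = 0.5 * (p.reshape(n, n) + p.reshape(n, n).T)
        inv = np.linalg.inv(theta)
        hp = inv @ pm @ inv + 2 * rho * pm
        return 0.5 * (hp + hp.T).ravel()

    res = minimize(fg, np.eye(n).ravel(), jac=True, hessp=hessp, method="trust-ncg",
                   options={"maxiter": 2000, "gtol": 1e-10})
    theta = res.x.reshape(n, n)
    return 0.5 * (theta + theta.T)


def make_cov_from_flat(s_flat: np.ndarray) -> CovMatrix:
    n = s_flat.shape[0]
    assert n % N_STATES == 0
    ell = n // N_STATES
    blocks = s_flat.reshape(ell, N_STATES, ell, N_STATES).transpose(0, 2, 1, 3)
    return CovMatrix(blocks=blocks)


class TestCov:
    def test_identical_sequences_zero(self):
        aln = Alignment.from_strings(["ACDE"] * 5)
        cov = compute_cov(compute_frequencies(aln))
        assert np.abs(cov.blocks).max() == 0

    def test_two_state_hand_values(self):
        aln = Alignment.from_strings(["AA", "CC"])
        s = compute_cov(compute_frequencies(aln)).blocks
        assert s[0, 1, 0, 0] == pytest.approx(0.25)
        assert s[0, 1, 0, 1] == pytest.approx(-0.25)

    def test_global_symmetry_and_zero_marginals(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(20, 6)).astype(np.int8))
        s = compute_cov(compute_frequencies(aln)).blocks
        assert np.allclose(s, s.transpose(1, 0, 3, 2))
        # exact frequencies make every block's row/column sums vanish
        assert np.allclose(s.sum(axis=2), 0, atol=1e-9)
        assert np.allclose(s.sum(axis=3), 0, atol=1e-9)

    def test_flat_view_symmetric(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(15, 4)).astype(np.int8))
        flat = compute_cov(compute_frequencies(aln)).flat
        assert np.allclose(flat, flat.T)


class TestPre:
    def test_identity_input_scalar_root(self):
        rho = DEFAULT_RHO
        n = 2 * N_STATES
        cov = make_cov_from_flat(np.eye(n))
        pre = compute_pre(cov, rho=rho, shrinkage=0.0)
        # positive root of 2*rho*t^2 + t - 1 = 0
        t_star = (-1 + np.sqrt(1 + 8 * rho)) / (4 * rho)
        assert np.allclose(pre.theta, t_star * np.eye(n), atol=1e-10)

    def test_small_rho_recovers_inverse(self, rng):
        n = N_STATES
        a = rng.standard_normal((n, n))
        s_flat = a @ a.T + n * np.eye(n)  # well conditioned
        cov = make_cov_from_flat(s_flat)
        pre = compute_pre(cov, rho=1e-10, shrinkage=0.0)
        assert np.allclose(pre.theta, np.linalg.inv(s_flat), atol=1e-4)

    def test_stationarity_and_positive_definite(self, rng):
        s_flat = rng.standard_normal((N_STATES, N_STATES))
        s_flat = 0.5 * (s_flat + s_flat.T)
        cov = make_cov_from_flat(s_flat)
        pre = compute_pre(cov, shrinkage=0.0)
        assert np.linalg.eigvalsh(pre.theta).min() > 0
        resid = s_flat - np.linalg.inv(pre.theta) + 2 * pre.rho * pre.theta
        assert np.abs(resid).max() <= 1e-6 * np.abs(s_flat).max()

    def test_matches_numeric_minimizer(self, rng):
        rho = 1e-2
        n = N_STATES
        s_flat = rng.standard_normal((n, n))
        s_flat = 0.5 * (s_flat + s_flat.T)
        pre = compute_pre(make_cov_from_flat(s_flat), rho=rho, shrinkage=0.0)
        theta_num = numeric_pre_minimizer(s_flat, rho)
        assert np.abs(pre.theta - theta_num).max() <= 1e-5


class TestPlm:
    def test_gradient_matches_finite_differences(self, rng):
        ell, n = 4, 6
        aln = Alignment(rng.integers(0, 21, size=(n, ell)).astype(np.int8))
        x = aln.one_hot().reshape(n, ell * N_STATES)
        w = rng.random(n) + 0.5
        n_par = ell * N_STATES + (ell * N_STATES) ** 2
        params = 0.1 * rng.standard_normal(n_par)
        _, grad = plm_objective(params, x, w, 0.01, 0.1)
        idx = rng.choice(n_par, size=40, replace=False)
        h = 1e-6
        for k in idx:
            pp, pm = params.copy(), params.copy()
            pp[k] += h
            pm[k] -= h
            fd = (plm_objective(pp, x, w, 0.01, 0.1)[0]
                  - plm_objective(pm, x, w, 0.01, 0.1)[0]) / (2 * h)
            denom = max(abs(fd), abs(grad[k]), 1e-8)
            assert abs(fd - grad[k]) / denom <= 1e-5

    def test_copied_columns_attain_top_coupling(self, rng):
        ell, n = 6, 400
        codes = rng.integers(0, 20, size=(n, ell))
        codes[:, 5] = codes[:, 2]  # perfectly correlated pair
        aln = Alignment(codes.astype(np.int8))
        model = compute_plm(aln, maxiter=150)
        scores = frobenius_score(model).scores
        iu, ju = np.triu_indices(ell, k=1)
        best = (iu[np.argmax(scores[iu, ju])], ju[np.argmax(scores[iu, ju])])
        assert best == (2, 5)

    def test_iid_columns_pass_permutation_null(self, rng):
        ell, n = 6, 300
        codes = rng.integers(0, 20, size=(n, ell)).astype(np.int8)

        def max_coupling(c):
            m = compute_plm(Alignment(c), maxiter=60)
            sc = frobenius_score(m).scores
            return sc[np.triu_indices(ell, k=1)].max()

        observed = max_coupling(codes)
        null = []
        for _ in range(6):
            perm = codes.copy()
            for col in range(ell):
                perm[:, col] = perm[rng.permutation(n), col]
            null.append(max_coupling(perm))
        # i.i.d. columns carry no coupling signal beyond the permutation null
        assert observed <= max(null) * 1.05

    def test_symmetry_and_zero_diagonal(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(30, 5)).astype(np.int8))
        model = compute_plm(aln, maxiter=60)
        assert np.allclose(model.J, model.J.transpose(1, 0, 3, 2))
        for i in range(5):
            assert np.all(model.J[i, i] == 0)

    def test_weight_scale_invariance(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(25, 4)).astype(np.int8))
        w = rng.random(25) + 0.1
        m1 = compute_plm(aln, weights=w, maxiter=80)
        m2 = compute_plm(aln, weights=7.5 * w, maxiter=80)
        assert np.allclose(m1.J, m2.J, atol=1e-6)


class TestScores:
    def test_frobenius_examples(self, rng):
        blocks = np.zeros((4, 4, 21, 21))
        assert np.all(frobenius_score(blocks).scores == 0)
        blocks[1, 2, 3, 4] = -2.5
        blocks[2, 1, 4, 3] = -2.5
        sm = frobenius_score(blocks)
        assert sm.scores[1, 2] == pytest.approx(2.5)
        random_block = rng.standard_normal((21, 21))
        blocks[0, 3] = random_block
        blocks[3, 0] = random_block.T
        sm = frobenius_score(blocks, exclude_gap=False)
        assert sm.scores[0, 3] == pytest.approx(np.sqrt((random_block ** 2).sum()))

    def test_frobenius_gap_exclusion(self):
        blocks = np.zeros((3, 3, 21, 21))
        blocks[0, 1, 20, 20] = 9.0  # gap-gap entry only
        blocks[1, 0, 20, 20] = 9.0
        assert frobenius_score(blocks, exclude_gap=True).scores[0, 1] == 0
        assert frobenius_score(blocks, exclude_gap=False).scores[0, 1] == 9.0

    def test_apc_constant_matrix_zeroes(self):
        s = np.full((5, 5), 3.0)
        np.fill_diagonal(s, 0)
        out = apc_correct(PairScoreMap(scores=s))
        assert np.allclose(out.scores, 0, atol=1e-12)

    def test_apc_dominant_pair_stays_argmax(self):
        s = np.full((4, 4), 1.0)
        np.fill_diagonal(s, 0)
        s[0, 2] = s[2, 0] = 5.0
        out = apc_correct(PairScoreMap(scores=s)).scores
        iu, ju = np.triu_indices(4, k=1)
        best = np.argmax(out[iu, ju])
        assert (iu[best], ju[best]) == (0, 2)

    def test_apc_symmetry_and_rank_one(self, rng):
        v = rng.random(6) + 0.5
        s = np.outer(v, v)
        np.fill_diagonal(s, 0)
        out = apc_correct(PairScoreMap(scores=s)).scores
        assert np.allclose(out, out.T)
        # APC removes a rank-one background almost entirely (the diagonal
        # exclusion in the means leaves a small residual)
        assert np.abs(out).max() <= 0.15 * s.max()

    def test_apc_all_zero_warns(self):
        with pytest.warns(RuntimeWarning):
            out = apc_correct(PairScoreMap(scores=np.zeros((4, 4))))
        assert np.all(out.scores == 0)


class TestFeatureTensor:
    def test_round_trip_and_shape(self, rng):
        blocks = rng.standard_normal((7, 7, 21, 21))
        tensor = assemble_feature_tensor(blocks)
        assert tensor.shape == (7, 7, 441)
        assert np.allclose(tensor_to_blocks(tensor), blocks, atol=1e-6)

    def test_channel_symmetry_for_cov(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(12, 5)).astype(np.int8))
        t = assemble_feature_tensor(compute_cov(compute_frequencies(aln)))
        a, b = 3, 17
        assert np.allclose(t[:, :, 21 * a + b], t[:, :, 21 * b + a].T)

    def test_channel_order(self):
        blocks = np.zeros((2, 2, 21, 21))
        blocks[0, 1, 2, 5] = 1.0
        tensor = assemble_feature_tensor(blocks)
        assert tensor[0, 1, 21 * 2 + 5] == 1.0

    def test_negate_flag(self, rng):
        blocks = rng.standard_normal((3, 3, 21, 21))
        assert np.allclose(assemble_feature_tensor(blocks, negate=True),
                           -assemble_feature_tensor(blocks))


class TestWeightScaleInvariance:
    def test_cov_pre_invariant_under_weight_scaling(self, rng):
        aln = Alignment(rng.integers(0, 21, size=(20, 4)).astype(np.int8))
        w = rng.random(20) + 0.1
        s1 = compute_frequencies(aln, weights=w)
        s2 = compute_frequencies(aln, weights=4.2 * w)
        c1, c2 = compute_cov(s1), compute_cov(s2)
        assert np.allclose(c1.blocks, c2.blocks)
        assert np.allclose(compute_pre(c1).theta, compute_pre(c2).theta)
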