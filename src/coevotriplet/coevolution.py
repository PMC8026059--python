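"""The raw coevolutionary feature triplet: COV, PRE and PLM.

Three global statistical views of the same alignment, each an L x L grid of
21 x 21 state-pair blocks (441 channels):

* COV — the covariance tensor S_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b):
  marginal dependency, including transitive correlation.
* PRE — the ridge-regularized precision matrix Theta minimizing
  G(Theta) = tr(S Theta) - log|Theta| + rho * sum ||Theta_ij||^2,
  the Gaussian (mean-field) approximation to direct couplings. The
  minimizer has a closed form per eigenvalue of S: with S = U diag(s) U',
  Theta = U diag(theta) U' where theta_k solves 2 rho theta^2 + s theta - 1 = 0
  (positive root), which is exactly where the gradient
  S - Theta^{-1} + 2 rho Theta vanishes.
* PLM — the couplings J of a 21-state Potts model fitted by weighted
  pseudolikelihood maximization: each site's conditional distribution
  P(sigma_l | sigma_{\\l}) = softmax_a( h_l(a) + sum_{k != l} J_lk(a, sigma_k) )
  is a multinomial regression on the rest of the sequence; the summed
  weighted negative log conditional likelihood plus L2 penalties is
  minimized by L-BFGS and J is symmetrized afterwards.

The raw blocks are what the downstream network consumes. The classical
pair scores (Frobenius norm of each block, then average product correction)
are provided as the unsupervised baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from coevotriplet.alphabet import N_STATES
from coevotriplet.msa import Alignment, WeightedStats, compute_frequencies

__all__ = [
    "CovMatrix",
    "PrecisionMatrix",
    "PottsModel",
    "PairScoreMap",
    "compute_cov",
    "compute_pre",
    "compute_plm",
    "plm_objective",
    "frobenius_score",
    "apc_correct",
    "assemble_feature_tensor",
    "tensor_to_blocks",
]

#: default ridge strength of the precision-matrix objective, rho = e^-6
DEFAULT_RHO: float = float(np.exp(-6.0))


@dataclass
class CovMatrix:
    """Covariance blocks S[i, j, a, b] with a flattened 21L x 21L view."""

    blocks: np.ndarray  # (L, L, 21, 21)

    @property
    def length(self) -> int:
        return self.blocks.shape[0]

    @property
    def flat(self) -> np.ndarray:
        ell = self.length
        return self.blocks.transpose(0, 2, 1, 3).reshape(ell * N_STATES, ell * N_STATES)


@dataclass
class PrecisionMatrix:
    """Ridge-regularized precision matrix Theta (flattened, symmetric PD)."""

    theta: np.ndarray  # (21L, 21L)
    rho: float = DEFAULT_RHO
    shrinkage: float = 0.0

    @property
    def length(self) -> int:
        return self.theta.shape[0] // N_STATES

    @property
    def blocks(self) -> np.ndarray:
        ell = self.length
        return self.theta.reshape(ell, N_STATES, ell, N_STATES).transpose(0, 2, 1, 3)


@dataclass
class PottsModel:
    """A 21-state Potts model: fields h (L, 21) and couplings J (L, L, 21, 21).

    Doubles as the simulator's ground truth and as the PLM feature. The
    couplings satisfy J[i, i] = 0 and, once symmetrized,
    J[i, j, a, b] = J[j, i, b, a].
    """

    h: np.ndarray
    J: np.ndarray
    lambda_h: float = 0.0
    lambda_J: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.h.ndim != 2 or self.h.shape[1] != N_STATES:
            raise ValueError("h must be (L, 21)")
        ell = self.h.shape[0]
        if self.J.shape != (ell, ell, N_STATES, N_STATES):
            raise ValueError("J must be (L, L, 21, 21)")

    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def blocks(self) -> np.ndarray:
        return self.J

    def symmetrized(self) -> "PottsModel":
        """J <- (J_ij + J_ji^T) / 2, with zeroed self-couplings."""
        j = 0.5 * (self.J + self.J.transpose(1, 0, 3, 2))
        idx = np.arange(self.length)
        j[idx, idx] = 0.0
        return PottsModel(self.h.copy(), j, self.lambda_h, self.lambda_J, self.converged)


@dataclass
class PairScoreMap:
    """Symmetric L x L pair scores with ranking-exclusion bookkeeping."""

    scores: np.ndarray
    method: str = "plm"
    apc_applied: bool = False
    min_separation: int = 1

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def masked(self) -> np.ndarray:
        """Scores with the diagonal band |i-j| < min_separation at the minimum."""
        s = self.scores.copy()
        ell = self.length
        i, j = np.indices((ell, ell))
        band = np.abs(i - j) < max(1, self.min_separation)
        fill = s[~band].min() if (~band).any() else 0.0
        s[band] = fill
        return s

    def top_pairs(self, k: int, min_separation: int | None = None) -> list[tuple[int, int]]:
        """Top-k unordered pairs (i < j) by descending score, ties by (i, j)."""
        sep = self.min_separation if min_separation is None else min_separation
        ell = self.length
        iu, ju = np.triu_indices(ell, k=max(1, sep))
        vals = self.scores[iu, ju]
        order = np.lexsort((ju, iu, -vals))
        return [(int(iu[o]), int(ju[o])) for o in order[:k]]


def compute_cov(stats: WeightedStats) -> CovMatrix:
    """Covariance tensor S[i,j,a,b] = f2[i,j,a,b] - f1[i,a] f1[j,b]."""
    if stats.f1 is None or stats.f2 is None:
        raise ValueError("stats must carry f1 and f2 (run compute_frequencies)")
    f1, f2 = stats.f1, stats.f2
    if f2.shape != (f1.shape[0], f1.shape[0], N_STATES, N_STATES):
        raise ValueError("f1/f2 shape mismatch")
    blocks = f2 - np.einsum("ia,jb->ijab", f1, f1)
    return CovMatrix(blocks=blocks)


def compute_pre(cov: CovMatrix, rho: float = DEFAULT_RHO,
                shrinkage: float = 0.1) -> PrecisionMatrix:
    """Closed-form minimizer of the ridge-penalized Gaussian likelihood.

    The (optionally shrunk) covariance is eigendecomposed and each
    eigenvalue s is mapped to theta = (-s + sqrt(s^2 + 8 rho)) / (4 rho),
    the positive root of the per-eigenvalue stationarity condition
    2 rho theta^2 + s theta - 1 = 0. The result is symmetric positive
    definite for any symmetric input and any rho > 0.

    ``shrinkage`` gamma blends S toward mean(diag(S)) * I before the
    decomposition to stabilize the spectrum of rank-deficient finite-sample
    covariances; gamma = 0 reproduces the bare objective's minimizer.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    s = cov.flat
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("flattened covariance must be symmetric")
    s = 0.5 * (s + s.T)
    if shrinkage:
        mu = float(np.mean(np.diag(s)))
        s = (1.0 - shrinkage) * s + shrinkage * mu * np.eye(s.shape[0])
    if not np.all(np.isfinite(s)):
        raise ValueError("covariance contains non-finite entries")
    evals, evecs = np.linalg.eigh(s)
    theta_evals = (-evals + np.sqrt(evals * evals + 8.0 * rho)) / (4.0 * rho)
    theta = (evecs * theta_evals) @ evecs.T
    theta = 0.5 * (theta + theta.T)
    return PrecisionMatrix(theta=theta, rho=rho, shrinkage=shrinkage)


def _coupling_mask(ell: int, dtype=np.float64) -> np.ndarray:
    """(21L, 21L) mask that zeroes the 21 x 21 self-coupling diagonal blocks."""
    mask = np.ones((ell * N_STATES, ell * N_STATES), dtype=dtype)
    for i in range(ell):
        mask[i * N_STATES:(i + 1) * N_STATES, i * N_STATES:(i + 1) * N_STATES] = 0.0
    return mask


def plm_objective(params: np.ndarray, x_flat: np.ndarray, weights: np.ndarray,
                  lambda_h: float, lambda_J: float) -> tuple[float, np.ndarray]:
    """Weighted negative log-pseudolikelihood with L2 penalties, and its gradient.

    ``params`` packs h (L*21) followed by the coupling matrix J (21L * 21L,
    row-major over (l, a, k, b)); ``x_flat`` is the (N, 21L) one-hot
    alignment. Self-coupling blocks are projected out of both the value and
    the gradient, so they stay exactly zero under gradient descent from a
    zero start.
    """
    n_seq, lq = x_flat.shape
    ell = lq // N_STATES
    h = params[: ell * N_STATES].reshape(ell, N_STATES)
    jmat = params[ell * N_STATES:].reshape(lq, lq)
    mask = _coupling_mask(ell, dtype=jmat.dtype)
    jmat = jmat * mask

    logits = x_flat @ jmat.T  # (N, 21L): logits[m, (l,a)] = sum_kb J[(l,a),(k,b)] x[m,(k,b)]
    logits = logits.reshape(n_seq, ell, N_STATES) + h[None]
    mx = logits.max(axis=2, keepdims=True)
    ex = np.exp(logits - mx)
    z = ex.sum(axis=2)
    lse = mx[..., 0] + np.log(z)
    x3 = x_flat.reshape(n_seq, ell, N_STATES)
    true_logit = (logits * x3).sum(axis=2)
    nll = float(np.sum(weights[:, None] * (lse - true_logit)))

    probs = ex / z[..., None]
    g = weights[:, None, None] * (probs - x3)  # dNLL/dlogits
    grad_h = g.sum(axis=0)
    gf = g.reshape(n_seq, lq)
    grad_j = (gf.T @ x_flat) * mask

    loss = nll + lambda_h * float(np.sum(h * h)) + lambda_J * float(np.sum(jmat * jmat))
    grad_h = grad_h + 2.0 * lambda_h * h
    grad_j = grad_j + 2.0 * lambda_J * jmat
    grad = np.concatenate([grad_h.ravel(), grad_j.ravel()])
    return loss, grad


def compute_plm(aln: Alignment, weights: np.ndarray | None = None,
                lambda_h: float = 0.01, lambda_J: float | None = None,
                maxiter: int = 500, tol: float = 1e-4,
                symmetrize: bool = True) -> PottsModel:
    """Fit Potts fields and couplings by weighted pseudolikelihood maximization.

    Defaults follow the common pseudolikelihood-DCA convention:
    lambda_h = 0.01 and lambda_J = 0.2 * (L - 1). Weights are rescaled to
    sum to N before fitting, so the fit depends only on relative weights
    (and equals the unweighted fit when all sequences are unique).
    Optimization is L-BFGS from a zero start (the objective is smooth and
    convex in the asymmetric parametrization); ``tol`` is the
    projected-gradient tolerance and ``maxiter`` the iteration cap.
    Non-convergence is reported via ``PottsModel.converged`` and a warning,
    with the partial fit returned.
    """
    if aln.n_sequences < 2:
        raise ValueError("PLM needs at least two sequences")
    if aln.length < 2:
        raise ValueError("PLM needs at least two columns")
    ell = aln.length
    if weights is None:
        weights = np.ones(aln.n_sequences)
    weights = np.asarray(weights, dtype=np.float64)
    weights = weights * (aln.n_sequences / weights.sum())
    if lambda_J is None:
        lambda_J = 0.2 * (ell - 1)
    x_flat = aln.one_hot(dtype=np.float64).reshape(aln.n_sequences, ell * N_STATES)
    n_par = ell * N_STATES + (ell * N_STATES) ** 2
    x0 = np.zeros(n_par)
    res = minimize(plm_objective, x0, args=(x_flat, weights, lambda_h, lambda_J),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 2 * maxiter + 50, "gtol": tol})
    h = res.x[: ell * N_STATES].reshape(ell, N_STATES)
    jmat = res.x[ell * N_STATES:].reshape(ell * N_STATES, ell * N_STATES)
    jmat *= _coupling_mask(ell)
    j = jmat.reshape(ell, N_STATES, ell, N_STATES).transpose(0, 2, 1, 3)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"PLM optimizer stopped early: {res.message}", RuntimeWarning)
    model = PottsModel(h=h, J=j, lambda_h=lambda_h, lambda_J=lambda_J, converged=converged)
    return model.symmetrized() if symmetrize else model


def _blocks_of(feature) -> np.ndarray:
    if isinstance(feature, np.ndarray):
        if feature.ndim != 4:
            raise ValueError("expected (L, L, 21, 21) blocks")
        return feature
    if hasattr(feature, "blocks"):
        return feature.blocks
    raise TypeError(f"cannot extract coupling blocks from {type(feature).__name__}")


def frobenius_score(feature, exclude_gap: bool = True,
                    method: str | None = None) -> PairScoreMap:
    """Frobenius norm of each 21 x 21 (or gap-excluded 20 x 20) block.

    The sign of the underlying potentials is ignored by construction; the
    diagonal is zeroed.
    """
    blocks = _blocks_of(feature)
    sub = blocks[:, :, :20, :20] if exclude_gap else blocks
    scores = np.sqrt(np.sum(sub * sub, axis=(2, 3)))
    scores = 0.5 * (scores + scores.T)
    np.fill_diagonal(scores, 0.0)
    if method is None:
        method = {"CovMatrix": "cov", "PrecisionMatrix": "pre",
                  "PottsModel": "plm"}.get(type(feature).__name__, "raw")
    return PairScoreMap(scores=scores, method=method, apc_applied=False)


def apc_correct(raw: PairScoreMap) -> PairScoreMap:
    """Average product correction of a symmetric nonnegative score matrix.

    corrected[i, j] = raw[i, j] - mean_i(raw) * mean_j(raw) / mean(raw),
    with all means taken over off-diagonal entries; output re-symmetrized
    with a zero diagonal.
    """
    s = raw.scores
    ell = s.shape[0]
    off = ~np.eye(ell, dtype=bool)
    total = s[off].mean() if ell > 1 else 0.0
    if total == 0:
        warnings.warn("APC on an all-zero score matrix; returning zeros", RuntimeWarning)
        return PairScoreMap(np.zeros_like(s), raw.method, True, raw.min_separation)
    row = s.sum(axis=1) / (ell - 1)  # diagonal is zero, so the sum skips it
    corrected = s - np.outer(row, row) / total
    corrected = 0.5 * (corrected + corrected.T)
    np.fill_diagonal(corrected, 0.0)
    return PairScoreMap(scores=corrected, method=raw.method, apc_applied=True,
                        min_separation=raw.min_separation)


def assemble_feature_tensor(feature, negate: bool = False) -> np.ndarray:
    """Pack coupling blocks into the (L, L, 441) network input tensor.

    Channel c = 21*a + b holds the (a, b) entry of block (i, j). ``negate``
    flips the sign (the precision feature can be fed as -Theta under the
    negative-inverse-covariance convention).
    """
    blocks = _blocks_of(feature)
    ell = blocks.shape[0]
    tensor = blocks.reshape(ell, ell, N_STATES * N_STATES)
    tensor = np.ascontiguousarray(tensor, dtype=np.float32)
    return -tensor if negate else tensor


def tensor_to_blocks(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`assemble_feature_tensor` (exact round trip)."""
    ell = tensor.shape[0]
    if tensor.shape != (ell, ell, N_STATES * N_STATES):
        raise ValueError("expected (L, L, 441)")
    return tensor.reshape(ell, ell, N_STATES, N_STATES)
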