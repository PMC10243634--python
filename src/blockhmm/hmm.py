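"""Exact classical HMM algorithms for univariate Gaussian emissions.

Log-space forward, backward, Viterbi decoding and Baum-Welch
reestimation for a hidden Markov model with one univariate Gaussian
emission density per state.  These are the reference algorithms that the
block-compressed variants in :mod:`blockhmm.compressed` approximate, and
they are usable on their own.

All probabilities live in the log domain throughout; sums of
probabilities are computed with the log-sum-exp trick (factoring out the
per-step maximum), so no scaling coefficients are needed.  State and
time indices are 0-based.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HMMModel",
    "TrellisResult",
    "PosteriorStats",
    "log_emission",
    "forward",
    "backward",
    "viterbi",
    "posterior_stats",
    "reestimate",
    "baum_welch",
]

#: Smallest admissible emission variance.  Reestimation can drive a
#: state's variance to zero on degenerate clusters (e.g. a state owning
#: a single observation); the floor keeps the model valid.
VARIANCE_FLOOR = 1e-8

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class HMMModel:
    """Gaussian-emission HMM, λ = (N, A, θ, π).

    Parameters
    ----------
    trans
        N×N row-stochastic transition matrix ``A``.
    means, variances
        Per-state emission mean μ_j and variance σ_j² (variances
        strictly positive).
    init
        Length-N initial state distribution π.
    """

    trans: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    init: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        object.__setattr__(self, "init", np.asarray(self.init, dtype=float))
        n = self.trans.shape[0]
        if self.trans.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if self.means.shape != (n,) or self.variances.shape != (n,) or self.init.shape != (n,):
            raise ValueError("means, variances and init must have length n_states")
        if np.any(self.trans < 0) or np.any(self.trans > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.trans.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            bad = int(np.argmax(np.abs(self.trans.sum(axis=1) - 1.0)))
            raise ValueError(f"transition row {bad} does not sum to 1")
        if np.any(self.init < 0) or np.any(self.init > 1):
            raise ValueError("initial probabilities must lie in [0, 1]")
        if not np.isclose(self.init.sum(), 1.0, rtol=0, atol=1e-12):
            raise ValueError("initial distribution does not sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    def log_trans(self) -> np.ndarray:
        """log A with exact zeros mapped to -inf (no warning)."""
        with np.errstate(divide="ignore"):
            return np.log(self.trans)

    def log_init(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.init)


@dataclass
class TrellisResult:
    """Dynamic-programming tables of a forward / backward / Viterbi pass.

    ``log_alpha``/``log_beta`` are T×N; ``log_delta``/``psi`` are filled
    by Viterbi only.  ``log_likelihood`` is log p(y|λ); ``log_best`` is
    the Viterbi score log P*.
    """

    log_alpha: np.ndarray | None = None
    log_beta: np.ndarray | None = None
    log_delta: np.ndarray | None = None
    psi: np.ndarray | None = None
    log_likelihood: float | None = None
    log_best: float | None = None


@dataclass
class PosteriorStats:
    """State posteriors γ_t(i) (T×N) and pair posteriors ξ_t(i,j) ((T-1)×N×N)."""

    xi: np.ndarray
    gamma: np.ndarray


def log_emission(y, mean, variance):
    """log N(y | mean, variance), broadcasting over any argument."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be strictly positive")
    y = np.asarray(y, dtype=float)
    out = -((y - mean) ** 2) / (2.0 * variance) - 0.5 * np.log(variance) - _HALF_LOG_2PI
    return out if out.ndim else float(out)


def _check_obs(obs) -> np.ndarray:
    y = np.asarray(obs, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("observation sequence must not be empty")
    if not np.all(np.isfinite(y)):
        raise ValueError("observations must be finite")
    return y


def _log_obs_matrix(model: HMMModel, y: np.ndarray) -> np.ndarray:
    """T×N matrix of log L_j(t) = log N(y_t | μ_j, σ_j²)."""
    return log_emission(y[:, None], model.means[None, :], model.variances[None, :])


def _lse_step_forward(log_vec: np.ndarray, trans: np.ndarray) -> np.ndarray:
    # logsum_i(v_i + log A_ij) via shared-max factoring; exact because
    # A >= 0 and exp(v - m) is overflow-safe.
    m = log_vec.max()
    if not np.isfinite(m):
        return np.full_like(log_vec, -np.inf)
    return np.log(np.exp(log_vec - m) @ trans) + m


def forward(model: HMMModel, obs) -> TrellisResult:
    """Forward pass: log α_t(i) and total log-likelihood log p(y|λ)."""
    y = _check_obs(obs)
    T, N = y.size, model.n_states
    logB = _log_obs_matrix(model, y)
    la = np.empty((T, N))
    la[0] = model.log_init() + logB[0]
    with np.errstate(divide="ignore"):
        for t in range(1, T):
            la[t] = _lse_step_forward(la[t - 1], model.trans) + logB[t]
    ll = _logsumexp(la[-1])
    return TrellisResult(log_alpha=la, log_likelihood=float(ll))


def backward(model: HMMModel, obs) -> TrellisResult:
    """Backward pass: log β_t(j); β_{T-1} ≡ 1."""
    y = _check_obs(obs)
    T, N = y.size, model.n_states
    logB = _log_obs_matrix(model, y)
    lb = np.empty((T, N))
    lb[-1] = 0.0
    with np.errstate(divide="ignore"):
        for t in range(T - 2, -1, -1):
            v = lb[t + 1] + logB[t + 1]
            m = v.max()
            if np.isfinite(m):
                lb[t] = np.log(model.trans @ np.exp(v - m)) + m
            else:
                lb[t] = -np.inf
    ll = _logsumexp(model.log_init() + logB[0] + lb[0])
    return TrellisResult(log_beta=lb, log_likelihood=float(ll))


def viterbi(model: HMMModel, obs) -> tuple[float, np.ndarray]:
    """Most likely state path via max-product recursion.

    Returns ``(log P*, q*)``.  Ties in the argmax are broken toward the
    smallest state index so decoded paths are reproducible.
    """
    y = _check_obs(obs)
    T, N = y.size, model.n_states
    logB = _log_obs_matrix(model, y)
    logA = model.log_trans()
    ld = np.empty((T, N))
    psi = np.zeros((T, N), dtype=np.intp)
    ld[0] = model.log_init() + logB[0]
    for t in range(1, T):
        scores = ld[t - 1][:, None] + logA  # N×N: i -> j
        psi[t] = np.argmax(scores, axis=0)
        ld[t] = scores[psi[t], np.arange(N)] + logB[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(ld[-1]))
    log_best = float(ld[-1, path[-1]])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return log_best, path


def posterior_stats(model: HMMModel, obs, fwd: TrellisResult, bwd: TrellisResult) -> PosteriorStats:
    """Pair posteriors ξ_t(i,j) and state posteriors γ_t(i).

    ξ_t(i,j) = α_t(i) A_ij L_j(t+1) β_{t+1}(j) / p(y|λ) for t < T-1;
    γ_t(i) = Σ_j ξ_t(i,j), with γ at the final step taken as
    α_{T-1} β_{T-1} / p(y|λ) (the pair posterior does not exist there
    but the emission reestimates sum over all T steps).
    """
    y = _check_obs(obs)
    T, N = y.size, model.n_states
    la, lb = fwd.log_alpha, bwd.log_beta
    if la is None or lb is None or la.shape != (T, N) or lb.shape != (T, N):
        raise ValueError("trellis dimensions do not match model/observations")
    ll = fwd.log_likelihood
    logB = _log_obs_matrix(model, y)
    gamma = np.exp(la + lb - ll)
    if T == 1:
        return PosteriorStats(xi=np.zeros((0, N, N)), gamma=gamma)
    with np.errstate(divide="ignore"):
        log_xi = (
            la[:-1, :, None]
            + model.log_trans()[None, :, :]
            + (logB[1:] + lb[1:])[:, None, :]
            - ll
        )
    xi = np.exp(log_xi)
    return PosteriorStats(xi=xi, gamma=gamma)


def reestimate(model: HMMModel, obs, stats: PosteriorStats) -> HMMModel:
    """One Baum-Welch M-step from accumulated ξ/γ statistics.

    π̄_i = γ_0(i); Ā_ij = Σ_t ξ_t(i,j) / Σ_t γ_t(i) (sums over t < T-1);
    μ̄_j and σ̄²_j are γ-weighted sample moments over all T steps, with
    the variance evaluated at the updated mean and floored at
    ``VARIANCE_FLOOR``.  Transitions that are exactly zero in the input
    model (topology constraints) remain exactly zero.
    """
    y = _check_obs(obs)
    T, N = y.size, model.n_states
    if stats.gamma.shape != (T, N):
        raise ValueError("posterior statistics do not match the observation length")
    gamma = stats.gamma
    new_init = gamma[0] / gamma[0].sum()

    trans_num = stats.xi.sum(axis=0)  # expected transition counts i->j
    trans_den = gamma[:-1].sum(axis=0) if T > 1 else np.zeros(N)
    new_trans = model.trans.copy()
    dead = trans_den <= 0
    if np.any(dead) and T > 1:
        warnings.warn(
            f"states {np.flatnonzero(dead).tolist()} have zero posterior mass; "
            "keeping their previous transition rows"
        )
    live = ~dead if T > 1 else np.zeros(N, dtype=bool)
    new_trans[live] = trans_num[live] / trans_den[live, None]
    # guard against tiny negative / >1 drift from floating point
    new_trans[live] = np.clip(new_trans[live], 0.0, 1.0)
    new_trans[live] /= new_trans[live].sum(axis=1, keepdims=True)

    occ = gamma.sum(axis=0)
    new_means = model.means.copy()
    new_vars = model.variances.copy()
    has_mass = occ > 0
    if np.any(~has_mass):
        warnings.warn(
            f"states {np.flatnonzero(~has_mass).tolist()} have zero emission mass; "
            "keeping their previous emission parameters"
        )
    m = has_mass
    new_means[m] = (gamma[:, m] * y[:, None]).sum(axis=0) / occ[m]
    sq = (y[:, None] - new_means[None, m]) ** 2
    new_vars[m] = np.maximum((gamma[:, m] * sq).sum(axis=0) / occ[m], VARIANCE_FLOOR)
    return HMMModel(trans=new_trans, means=new_means, variances=new_vars, init=new_init)


def baum_welch(
    model0: HMMModel,
    obs,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> tuple[HMMModel, list[float]]:
    """Maximum-likelihood training by iterated E/M steps.

    Iterates forward → backward → posteriors → reestimate until the
    log-likelihood improvement drops below ``tol`` or ``max_iter``
    reestimations have been performed.  Returns the trained model and
    the per-iteration log-likelihood trace (evaluated at the model
    *before* each reestimation, plus the final model's likelihood).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    y = _check_obs(obs)
    model = model0
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        fwd = forward(model, y)
        trace.append(fwd.log_likelihood)
        if fwd.log_likelihood - prev < tol and np.isfinite(prev):
            return model, trace
        prev = fwd.log_likelihood
        bwd = backward(model, y)
        stats = posterior_stats(model, y, fwd, bwd)
        model = reestimate(model, y, stats)
    trace.append(forward(model, y).log_likelihood)
    return model, trace


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if not np.isfinite(m):
        return float(m)
    return float(np.log(np.exp(v - m).sum()) + m)
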