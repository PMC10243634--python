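"""Forward, backward, Viterbi and Baum-Welch on blocks of sufficient statistics.

Instead of iterating over every observation, these recursions iterate
over the W blocks produced by :func:`blockhmm.wavelet.compress`,
assuming the hidden chain does not switch state inside a block (the
*weak path assumption*).  A block of length n_w spent in state j costs
(n_w − 1) self-transitions plus the product of its Gaussian emission
densities, which depends on the data only through n_w, Σ1_w and Σ2_w.
Collecting everything into one exponent gives

    E_w(j) = (2 μ_j Σ1_w − Σ2_w) / (2 σ_j²) + K(n_w, j),
    K(n_w, j) = (n_w − 1) log A_jj − n_w (log σ_j + μ_j²/(2σ_j²) + ½ log 2π),

and the forward recursion becomes
log α_w(j) = logsum_i(log α_{w−1}(i) + log A_ij) + E_w(j), an O(W N²)
pass.  When every block is a singleton (W = T) the recursions reduce
exactly to the classical ones; otherwise the resulting likelihood is an
approximation that is extremely accurate whenever the data really is
piecewise constant with noise.

The E-step quantities are exact posteriors of the block-constrained
model (paths constant within blocks), so the compressed Baum-Welch is a
true EM on that model and its likelihood trace is monotone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hmm import HMMModel, VARIANCE_FLOOR, _logsumexp
from .wavelet import Block, BlockSequence

__all__ = [
    "CompressedTrellis",
    "CompressedPosteriors",
    "block_exponent",
    "block_exponents",
    "compressed_forward",
    "compressed_backward",
    "compressed_viterbi",
    "compressed_posteriors",
    "compressed_reestimate",
    "compressed_baum_welch",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class CompressedTrellis:
    """Block-indexed trellis; row w refers to the END of block w."""

    log_alpha: np.ndarray | None = None
    log_beta: np.ndarray | None = None
    log_delta: np.ndarray | None = None
    psi: np.ndarray | None = None
    log_likelihood: float | None = None
    log_best: float | None = None


@dataclass
class CompressedPosteriors:
    """Block pair posteriors ξ_w(i,j) (W×N×N) and representative state
    posteriors γ_w(i) (W×N).

    ξ_w sums the per-step pair posteriors over the block, so
    Σ_j ξ_w(i,j) = n_w γ_w(i) for w < W−1 and (n_W − 1) γ_W(i) for the
    last block; γ_w is constant across the block's positions.
    """

    xi: np.ndarray
    gamma: np.ndarray


def block_exponents(model: HMMModel, blocks: BlockSequence) -> np.ndarray:
    """W×N matrix of E_w(j), the log-weight of spending block w in state j.

    A state with A_jj = 0 cannot host a block of length > 1: its
    exponent is −∞ there (the block is unreachable), while for
    singleton blocks the (n_w − 1) log A_jj term is exactly zero.
    """
    n = blocks.n.astype(float)[:, None]  # W×1
    s1 = blocks.s1[:, None]
    s2 = blocks.s2[:, None]
    mu = model.means[None, :]
    var = model.variances[None, :]
    diag = np.diag(model.trans)
    with np.errstate(divide="ignore"):
        log_diag = np.log(diag)[None, :]
    # (n-1)·log A_jj with the 0·(−inf) case resolved to 0
    self_term = (n - 1) * np.where(diag[None, :] > 0, log_diag, 0.0)
    self_term[np.broadcast_to((n > 1) & (diag[None, :] == 0), self_term.shape)] = -np.inf
    data_term = (2.0 * mu * s1 - s2) / (2.0 * var)
    const_term = -n * (0.5 * np.log(var) + mu**2 / (2.0 * var) + _HALF_LOG_2PI)
    return data_term + const_term + self_term


def block_exponent(block: Block, state_index: int, model: HMMModel) -> float:
    """E_w(j) for a single block/state pair (scalar convenience)."""
    if not 0 <= state_index < model.n_states:
        raise ValueError("state index out of range")
    single = BlockSequence(
        starts=np.array([block.start]),
        ends=np.array([block.end]),
        s1=np.array([block.s1]),
        s2=np.array([block.s2]),
    )
    return float(block_exponents(model, single)[0, state_index])


def compressed_forward(model: HMMModel, blocks: BlockSequence) -> CompressedTrellis:
    """Block-level forward pass; log-likelihood approximates log p(y|λ)."""
    W, N = blocks.W, model.n_states
    E = block_exponents(model, blocks)
    la = np.empty((W, N))
    la[0] = model.log_init() + E[0]
    with np.errstate(divide="ignore"):
        for w in range(1, W):
            m = la[w - 1].max()
            if np.isfinite(m):
                la[w] = np.log(np.exp(la[w - 1] - m) @ model.trans) + m + E[w]
            else:
                la[w] = -np.inf
    return CompressedTrellis(log_alpha=la, log_likelihood=_logsumexp(la[-1]))


def compressed_backward(model: HMMModel, blocks: BlockSequence) -> CompressedTrellis:
    """Block-level backward pass; β_W ≡ 1 and
    logsum_i α_w(i)β_w(i) is constant over w."""
    W, N = blocks.W, model.n_states
    E = block_exponents(model, blocks)
    lb = np.empty((W, N))
    lb[-1] = 0.0
    with np.errstate(divide="ignore"):
        for w in range(W - 2, -1, -1):
            v = E[w + 1] + lb[w + 1]
            m = v.max()
            if np.isfinite(m):
                lb[w] = np.log(model.trans @ np.exp(v - m)) + m
            else:
                lb[w] = -np.inf
    ll = _logsumexp(model.log_init() + E[0] + lb[0])
    return CompressedTrellis(log_beta=lb, log_likelihood=ll)


def compressed_viterbi(model: HMMModel, blocks: BlockSequence) -> tuple[float, np.ndarray]:
    """Best block-constant state assignment, expanded to a length-T path.

    log δ_w(j) = max_i(log δ_{w−1}(i) + log A_ij) + E_w(j), the
    max-product analogue of the block forward recursion; ties go to the
    smallest state index.
    """
    W, N = blocks.W, model.n_states
    E = block_exponents(model, blocks)
    logA = model.log_trans()
    ld = np.empty((W, N))
    psi = np.zeros((W, N), dtype=np.intp)
    ld[0] = model.log_init() + E[0]
    for w in range(1, W):
        scores = ld[w - 1][:, None] + logA
        psi[w] = np.argmax(scores, axis=0)
        ld[w] = scores[psi[w], np.arange(N)] + E[w]
    block_states = np.empty(W, dtype=np.intp)
    block_states[-1] = int(np.argmax(ld[-1]))
    log_best = float(ld[-1, block_states[-1]])
    for w in range(W - 2, -1, -1):
        block_states[w] = psi[w + 1, block_states[w + 1]]
    return log_best, blocks.expand_states(block_states)


def compressed_posteriors(
    model: HMMModel,
    blocks: BlockSequence,
    fwd: CompressedTrellis,
    bwd: CompressedTrellis,
) -> CompressedPosteriors:
    """Block-summed pair posteriors ξ_w and representative γ_w.

    For w < W−1:
        ξ_w(i,i) = [(n_w−1) α_w(i) β_w(i) + α_w(i) A_ii e^{E_{w+1}(i)} β_{w+1}(i)] / p
        ξ_w(i,j) = α_w(i) A_ij e^{E_{w+1}(j)} β_{w+1}(j) / p         (i ≠ j)
    For the last block: ξ_W(i,i) = (n_W−1) α_W(i) β_W(i) / p and 0 off
    the diagonal.  All products are assembled in the log domain and
    exponentiated only after subtracting log p, so nothing overflows.
    """
    W, N = blocks.W, model.n_states
    la, lb = fwd.log_alpha, bwd.log_beta
    if la is None or lb is None or la.shape != (W, N) or lb.shape != (W, N):
        raise ValueError("trellis dimensions do not match the block sequence")
    ll = fwd.log_likelihood
    E = block_exponents(model, blocks)
    gamma = np.exp(la + lb - ll)
    n = blocks.n.astype(float)
    xi = np.zeros((W, N, N))
    if W > 1:
        with np.errstate(divide="ignore"):
            log_cross = (
                la[:-1, :, None]
                + model.log_trans()[None, :, :]
                + (E[1:] + lb[1:])[:, None, :]
                - ll
            )
        xi[:-1] = np.exp(log_cross)
    idx = np.arange(N)
    xi[:, idx, idx] += (n[:, None] - 1.0) * gamma
    return CompressedPosteriors(xi=xi, gamma=gamma)


def compressed_reestimate(
    model: HMMModel, blocks: BlockSequence, post: CompressedPosteriors
) -> HMMModel:
    """One M-step from block posteriors.

    π̄_i = γ_1(i);  Ā_ij = Σ_w ξ_w(i,j) / (Σ_w n_w γ_w(i) − γ_W(i));
    μ̄_j = Σ_w γ_w(j) Σ1_w / Σ_w γ_w(j) n_w;
    σ̄²_j = Σ_w γ_w(j)[Σ2_w − 2 μ̄_j Σ1_w + n_w μ̄_j²] / Σ_w γ_w(j) n_w,
    floored.  Zero transitions stay exactly zero.  With singleton blocks
    all four formulas coincide with the classical reestimates.
    """
    W, N = blocks.W, model.n_states
    if post.gamma.shape != (W, N):
        raise ValueError("posteriors do not match the block sequence")
    gamma, xi = post.gamma, post.xi
    n = blocks.n.astype(float)

    new_init = gamma[0] / gamma[0].sum()

    trans_num = xi.sum(axis=0)
    trans_den = (n[:, None] * gamma).sum(axis=0) - gamma[-1]
    new_trans = model.trans.copy()
    dead = trans_den <= 0
    if np.any(dead):
        warnings.warn(
            f"states {np.flatnonzero(dead).tolist()} have zero posterior transition "
            "mass; keeping their previous transition rows"
        )
    live = ~dead
    new_trans[live] = trans_num[live] / trans_den[live, None]
    new_trans[live] = np.clip(new_trans[live], 0.0, 1.0)
    new_trans[live] /= new_trans[live].sum(axis=1, keepdims=True)

    occ = (gamma * n[:, None]).sum(axis=0)
    new_means = model.means.copy()
    new_vars = model.variances.copy()
    has_mass = occ > 0
    if np.any(~has_mass):
        warnings.warn(
            f"states {np.flatnonzero(~has_mass).tolist()} have zero emission mass; "
            "keeping their previous emission parameters"
        )
    m = has_mass
    new_means[m] = (gamma[:, m] * blocks.s1[:, None]).sum(axis=0) / occ[m]
    ss = (
        blocks.s2[:, None]
        - 2.0 * new_means[None, m] * blocks.s1[:, None]
        + n[:, None] * new_means[None, m] ** 2
    )
    new_vars[m] = np.maximum((gamma[:, m] * ss).sum(axis=0) / occ[m], VARIANCE_FLOOR)
    return HMMModel(trans=new_trans, means=new_means, variances=new_vars, init=new_init)


def compressed_baum_welch(
    model0: HMMModel,
    blocks: BlockSequence,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> tuple[HMMModel, list[float]]:
    """EM on the block-constrained model; blocks are fixed throughout.

    Compression happens once, before training; the block exponents are
    recomputed each iteration from the current parameters (they contain
    log A_jj, μ_j, σ_j).  Same stopping rule as the uncompressed
    trainer: improvement below ``tol`` or ``max_iter`` reestimations.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    model = model0
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        fwd = compressed_forward(model, blocks)
        trace.append(fwd.log_likelihood)
        if fwd.log_likelihood - prev < tol and np.isfinite(prev):
            return model, trace
        prev = fwd.log_likelihood
        bwd = compressed_backward(model, blocks)
        post = compressed_posteriors(model, blocks, fwd, bwd)
        model = compressed_reestimate(model, blocks, post)
    trace.append(compressed_forward(model, blocks).log_likelihood)
    return model, trace
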