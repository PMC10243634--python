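"""Independent brute-force oracles used by the tests.

Everything here enumerates paths explicitly and never calls the dynamic
programming code it is used to check.  Feasible only for tiny problems
(N^T or N^W terms).
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm


def path_log_prob(model, y, path) -> float:
    """log p(y, q | λ) of one explicit state path."""
    lp = np.log(model.init[path[0]]) + norm.logpdf(
        y[0], model.means[path[0]], np.sqrt(model.variances[path[0]])
    )
    for t in range(1, len(y)):
        lp += np.log(model.trans[path[t - 1], path[t]])
        lp += norm.logpdf(y[t], model.means[path[t]], np.sqrt(model.variances[path[t]]))
    return float(lp)


def enum_paths(model, y):
    """All (path, log p(y, q)) pairs."""
    N, T = model.n_states, len(y)
    out = []
    for path in itertools.product(range(N), repeat=T):
        with np.errstate(divide="ignore"):
            out.append((path, path_log_prob(model, y, path)))
    return out


def _logsum(values) -> float:
    v = np.asarray(values, dtype=float)
    m = v.max()
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(v - m).sum()))


def enum_log_likelihood(model, y) -> float:
    return _logsum([lp for _, lp in enum_paths(model, y)])


def enum_viterbi(model, y):
    """(best log-prob, best path) with ties toward the smaller path tuple."""
    paths = enum_paths(model, y)
    best = max(paths, key=lambda item: (item[1], tuple(-s for s in item[0])))
    return best[1], np.array(best[0])


def enum_posteriors(model, y):
    """Exact γ (T×N) and ξ ((T-1)×N×N) by path enumeration."""
    N, T = model.n_states, len(y)
    paths = enum_paths(model, y)
    ll = _logsum([lp for _, lp in paths])
    gamma = np.zeros((T, N))
    xi = np.zeros((T - 1, N, N))
    for path, lp in paths:
        w = np.exp(lp - ll)
        for t, s in enumerate(path):
            gamma[t, s] += w
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += w
    return gamma, xi


def enum_reestimate(model, y, gamma, xi):
    """Classical M-step accumulated directly from enumerated posteriors."""
    new_init = gamma[0]
    new_trans = xi.sum(axis=0) / gamma[:-1].sum(axis=0)[:, None]
    occ = gamma.sum(axis=0)
    new_means = (gamma * y[:, None]).sum(axis=0) / occ
    new_vars = (gamma * (y[:, None] - new_means[None, :]) ** 2).sum(axis=0) / occ
    return new_init, new_trans, new_means, new_vars


# ---------------------------------------------------------------- blocks

def block_assignment_log_prob(model, y, bounds, assign) -> float:
    """log p(y, q) of a block-constant path: state assign[w] on
    [bounds[w], bounds[w+1])."""
    with np.errstate(divide="ignore"):
        lp = np.log(model.init[assign[0]])
        for w, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            j = assign[w]
            if w > 0:
                lp += np.log(model.trans[assign[w - 1], j])
            lp += (e - s - 1) * np.log(model.trans[j, j])
            lp += norm.logpdf(y[s:e], model.means[j], np.sqrt(model.variances[j])).sum()
    return float(lp)


def enum_block_assignments(model, y, bounds):
    N, W = model.n_states, len(bounds) - 1
    return [
        (assign, block_assignment_log_prob(model, y, bounds, assign))
        for assign in itertools.product(range(N), repeat=W)
    ]


def enum_block_log_likelihood(model, y, bounds) -> float:
    return _logsum([lp for _, lp in enum_block_assignments(model, y, bounds)])


def enum_block_viterbi(model, y, bounds):
    items = enum_block_assignments(model, y, bounds)
    best = max(items, key=lambda item: (item[1], tuple(-s for s in item[0])))
    return best[1], np.array(best[0])


def enum_block_posteriors(model, y, bounds):
    """Block-constrained γ_w (W×N) and block-summed ξ_w (W×N×N)."""
    N, W = model.n_states, len(bounds) - 1
    n = np.diff(bounds)
    items = enum_block_assignments(model, y, bounds)
    ll = _logsum([lp for _, lp in items])
    gamma = np.zeros((W, N))
    pair = np.zeros((W - 1, N, N)) if W > 1 else np.zeros((0, N, N))
    for assign, lp in items:
        weight = np.exp(lp - ll)
        for w, s in enumerate(assign):
            gamma[w, s] += weight
        for w in range(W - 1):
            pair[w, assign[w], assign[w + 1]] += weight
    xi = np.zeros((W, N, N))
    if W > 1:
        xi[:-1] = pair
    idx = np.arange(N)
    xi[:, idx, idx] += (n[:, None] - 1.0) * gamma
    return gamma, xi, ll
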