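"""Model construction, data generation and the accuracy/convergence benchmark.

Models come in three topologies common in applications:

* ``fully_connected`` — every state reaches every other state;
* ``left_to_right``  — transitions i → j require i ≤ j; the final state
  is absorbing (it has no successor to spread mass over);
* ``circular``       — each state reaches only itself and its successor
  modulo N.

Self-transition probabilities are set to 1 − 10N/T, so a sequence of
length T contains on average 10N state switches; the remaining mass is
split uniformly over the out-neighbours the topology allows.  Emissions
are unit-variance Gaussians spaced so that adjacent states have a fixed
*state separation* η = |μ_a − μ_b| / (3(σ_a + σ_b)), i.e. Δμ = 6η:
η = 1 is easy (well-separated states), η = 0.1 is hard (heavily
overlapping densities).

The benchmark harness samples data from such a model, compresses it,
and runs evaluation, decoding and training in both the classical and
the compressed mode, recording the relative log-likelihood error, the
Viterbi path agreement, iteration counts and the compression ratio.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .compressed import compressed_baum_welch, compressed_forward, compressed_viterbi
from .hmm import HMMModel, VARIANCE_FLOOR, baum_welch, forward, viterbi
from .wavelet import compress

__all__ = [
    "TOPOLOGIES",
    "TopologySpec",
    "SimulationConfig",
    "build_model",
    "sample_sequence",
    "kmeans_init",
    "run_experiment",
    "match_means",
]

TOPOLOGIES = ("fully_connected", "left_to_right", "circular")


@dataclass(frozen=True)
class TopologySpec:
    kind: str
    n_states: int

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.kind!r}; expected one of {TOPOLOGIES}")
        if self.n_states < 2:
            raise ValueError("need at least 2 states for meaningful transitions")


@dataclass
class SimulationConfig:
    """One benchmark configuration.

    ``n_tests`` replicates are run, replicate r using seed
    ``seed + r`` so any single replicate can be re-run in isolation.
    ``n_train_restarts`` K-means initializations are tried per trainer
    and the restart with the best final log-likelihood is kept.
    """

    topology: TopologySpec = field(default_factory=lambda: TopologySpec("fully_connected", 2))
    T: int = 20000
    eta: float = 1.0
    n_tests: int = 10
    n_train_restarts: int = 1
    seed: int = 0
    tol: float = 1e-3
    max_iter: int = 100
    train: bool = True

    def __post_init__(self) -> None:
        if self.T <= 10 * self.topology.n_states:
            raise ValueError("T must exceed 10·N so self-transitions stay in (0, 1)")
        if self.eta <= 0:
            raise ValueError("state separation eta must be positive")


def _topology_adjacency(kind: str, N: int) -> np.ndarray:
    """Boolean N×N matrix of allowed transitions (including self-loops)."""
    adj = np.zeros((N, N), dtype=bool)
    if kind == "fully_connected":
        adj[:] = True
    elif kind == "left_to_right":
        adj = np.triu(np.ones((N, N), dtype=bool))
    elif kind == "circular":
        idx = np.arange(N)
        adj[idx, idx] = True
        adj[idx, (idx + 1) % N] = True
    else:
        raise ValueError(f"unknown topology {kind!r}")
    return adj


def topology_transitions(kind: str, N: int, T: int) -> np.ndarray:
    """Transition matrix with self-transition 1 − 10N/T and the rest of
    each row spread uniformly over the topology's out-neighbours."""
    if N == 1:
        return np.ones((1, 1))
    p_self = 1.0 - 10.0 * N / T
    if not 0.0 < p_self < 1.0:
        raise ValueError("T must exceed 10·N")
    adj = _topology_adjacency(kind, N)
    A = np.zeros((N, N))
    for i in range(N):
        out = np.flatnonzero(adj[i] & (np.arange(N) != i))
        if out.size == 0:
            if kind == "left_to_right" and i == N - 1:
                A[i, i] = 1.0  # absorbing final state
                continue
            raise ValueError(f"state {i} has no out-neighbours under {kind!r}")
        A[i, i] = p_self
        A[i, out] = (1.0 - p_self) / out.size
    return A


def build_model(spec: TopologySpec, T: int, eta: float) -> HMMModel:
    """Ground-truth model for a topology, length and state separation.

    Unit variances; means 0, 6η, 12η, … (Δμ = 3(σ_k + σ_{k+1})η = 6η);
    uniform initial distribution.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    N = spec.n_states
    A = topology_transitions(spec.kind, N, T)
    means = 6.0 * eta * np.arange(N, dtype=float)
    return HMMModel(
        trans=A,
        means=means,
        variances=np.ones(N),
        init=np.full(N, 1.0 / N),
    )


def sample_sequence(model: HMMModel, T: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and observations; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    N = model.n_states
    states = np.empty(T, dtype=np.intp)
    states[0] = rng.choice(N, p=model.init)
    # cumulative rows let us draw the whole chain with one uniform each
    cum = np.cumsum(model.trans, axis=1)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    y = model.means[states] + np.sqrt(model.variances[states]) * rng.standard_normal(T)
    return states, y


def kmeans_init(
    obs,
    N: int,
    T: int,
    seed: int,
    topology: str = "fully_connected",
) -> HMMModel:
    """Initial model estimate from K-means clustering of the observations.

    Cluster centers (sorted ascending for label stability) become the
    initial means, within-cluster variances the initial variances;
    transitions are the topology-uniform matrix with self-transition
    1 − 10N/T and π is uniform.
    """
    y = np.asarray(obs, dtype=float).ravel()
    if np.unique(y).size < N:
        raise ValueError("need at least N distinct observed values")
    for attempt in range(5):
        km = KMeans(n_clusters=N, n_init=3, random_state=(seed + 1000003 * attempt) % 2**31)
        labels = km.fit_predict(y[:, None])
        if np.unique(labels).size == N:
            break
    else:
        raise RuntimeError("K-means produced an empty cluster in 5 attempts")
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    means = centers[order]
    variances = np.empty(N)
    for k, lab in enumerate(order):
        variances[k] = max(np.var(y[labels == lab]), VARIANCE_FLOOR)
    return HMMModel(
        trans=topology_transitions(topology, N, T),
        means=means,
        variances=variances,
        init=np.full(N, 1.0 / N),
    )


def match_means(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Absolute mean errors after the optimal one-to-one relabeling."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(estimated[:, None] - truth[None, :])
    rows, cols = linear_sum_assignment(cost)
    return cost[rows, cols]


def run_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Run the benchmark; one row per replicate.

    Columns: log-likelihoods and relative error of evaluation, Viterbi
    path agreement fraction, iteration counts of both trainers (of the
    best restart), compression ratio T/W.  Iteration count = number of
    reestimation steps performed before the stopping rule fired.
    """
    records = []
    for r in range(config.n_tests):
        seed = config.seed + r
        try:
            records.append(_run_replicate(config, r, seed))
        except Exception as exc:  # replicate-level failure: log and skip
            warnings.warn(f"replicate {r} (seed {seed}) failed: {exc}")
    df = pd.DataFrame.from_records(records)
    skipped = config.n_tests - len(df)
    if skipped:
        warnings.warn(f"{skipped} of {config.n_tests} replicates failed and were skipped")
    return df


def _run_replicate(config: SimulationConfig, replicate: int, seed: int) -> dict:
    model = build_model(config.topology, config.T, config.eta)
    states, y = sample_sequence(model, config.T, seed)
    blocks = compress(y)

    ll_std = forward(model, y).log_likelihood
    ll_cmp = compressed_forward(model, blocks).log_likelihood
    rel_err = abs(ll_cmp - ll_std) / abs(ll_std)

    _, path_std = viterbi(model, y)
    _, path_cmp = compressed_viterbi(model, blocks)
    agreement = float(np.mean(path_std == path_cmp))

    rec = {
        "replicate": replicate,
        "seed": seed,
        "T": config.T,
        "W": blocks.W,
        "compression_ratio": config.T / blocks.W,
        "ll_standard": ll_std,
        "ll_compressed": ll_cmp,
        "rel_error": rel_err,
        "path_agreement": agreement,
    }
    if config.train:
        best_std = best_cmp = -np.inf
        iters_std = iters_cmp = 0
        for restart in range(config.n_train_restarts):
            init = kmeans_init(
                y, model.n_states, config.T, seed + 7919 * restart, config.topology.kind
            )
            m_std, trace_std = baum_welch(init, y, config.tol, config.max_iter)
            if trace_std[-1] > best_std:
                best_std, iters_std = trace_std[-1], len(trace_std) - 1
            m_cmp, trace_cmp = compressed_baum_welch(init, blocks, config.tol, config.max_iter)
            if trace_cmp[-1] > best_cmp:
                best_cmp, iters_cmp = trace_cmp[-1], len(trace_cmp) - 1
        rec.update(
            train_ll_standard=best_std,
            train_ll_compressed=best_cmp,
            iters_standard=iters_std,
            iters_compressed=iters_cmp,
        )
    return rec
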