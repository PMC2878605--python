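"""Mk-model likelihoods and stochastic character mapping of habitat use.

A continuous-time Markov (Mk) model describes transitions among the four
habitat states along the tree.  The module provides the pruning
log-likelihood, maximum-likelihood rate estimation (equal-rates or
all-rates-different), sampling of full character histories conditioned on the
tip states (stochastic character maps), and counting of independent origins
of each state on a map.

Rates are treated empirical-Bayes style: stochastic maps are drawn under the
ML point estimate of the transition rates rather than under a prior over
rates.  Endpoint-conditioned branch histories are drawn by rejection
sampling, falling back to uniformization after repeated rejection, which
guarantees termination on long branches with fixed unequal endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .tree_model import HABITAT_STATES, StochasticMap, Tree

#: Bounds for ML transition-rate optimization (per unit tree depth).
RATE_LO = 1e-8
RATE_HI = 1e3

#: Forward-rejection attempts per branch before switching to uniformization.
MAX_REJECTIONS = 1000


@dataclass
class MkModel:
    """Continuous-time Markov model of a discrete character.

    Parameters
    ----------
    states
        Ordered state labels; row/column order of ``Q``.
    Q
        Instantaneous rate matrix: nonnegative off-diagonals, rows sum to 0.
    root_prior
        Probability vector over states at the root (default uniform).
    structure
        ``"ER"`` (one symmetric rate) or ``"ARD"`` (all rates different).
    """

    states: tuple[str, ...]
    Q: np.ndarray
    root_prior: np.ndarray | None = None
    structure: str = "ER"

    def __post_init__(self):
        self.states = tuple(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError(f"Q must be {k}x{k}")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(self.Q).max())):
            raise ValueError("rows of Q must sum to zero")
        if self.root_prior is None:
            self.root_prior = np.full(k, 1.0 / k)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if abs(self.root_prior.sum() - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of ``Q`` (null-space of ``Q.T``)."""
        w, v = np.linalg.eig(self.Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def er_model(
    rate: float,
    states: Sequence[str] = HABITAT_STATES,
    root_prior: np.ndarray | None = None,
) -> MkModel:
    """Equal-rates Mk model: every off-diagonal entry equals ``rate``."""
    k = len(states)
    Q = np.full((k, k), float(rate))
    np.fill_diagonal(Q, -(k - 1) * float(rate))
    return MkModel(tuple(states), Q, root_prior, structure="ER")


def ard_model(
    rates: np.ndarray,
    states: Sequence[str] = HABITAT_STATES,
    root_prior: np.ndarray | None = None,
) -> MkModel:
    """All-rates-different Mk model from a full off-diagonal rate matrix."""
    Q = np.asarray(rates, dtype=float).copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return MkModel(tuple(states), Q, root_prior, structure="ARD")


def _tip_state_indices(tree: Tree, data: Mapping[str, str], states: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    out = np.empty(tree.n_tips, dtype=np.intp)
    for tip, label in enumerate(tree.labels):
        if label not in data:
            raise KeyError(f"tip {label!r} has no observed habitat state")
        s = data[label]
        if s not in idx:
            raise KeyError(f"tip {label!r} has unknown state {s!r}")
        out[tip] = idx[s]
    return out


def _branch_transition_matrices(tree: Tree, Q: np.ndarray) -> list[np.ndarray | None]:
    """``expm(Q t)`` per node's parent branch, cached over repeated lengths."""
    cache: dict[float, np.ndarray] = {}
    out: list[np.ndarray | None] = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t = float(tree.blen[v])
        if t not in cache:
            cache[t] = expm(Q * t)
        out[v] = cache[t]
    return out


def _partials(
    tree: Tree, data: Mapping[str, str], model: MkModel
) -> tuple[np.ndarray, float, list[np.ndarray | None]]:
    """Postorder conditional likelihoods, per-node rescaled.

    Returns ``(L, log_scale, P)`` where ``L[v]`` is the rescaled conditional
    likelihood of the data below ``v`` given the state at ``v``, ``log_scale``
    the accumulated log of the rescaling constants, and ``P`` the per-branch
    transition matrices.
    """
    k = model.n_states
    tips = _tip_state_indices(tree, data, model.states)
    P = _branch_transition_matrices(tree, model.Q)
    L = np.zeros((tree.n_nodes, k))
    log_scale = 0.0
    for v in tree.postorder:
        if not tree.children[v]:
            L[v, tips[v]] = 1.0
        else:
            vec = np.ones(k)
            for c in tree.children[v]:
                vec = vec * (P[c] @ L[c])
            m = vec.max()
            if m <= 0:
                raise FloatingPointError("conditional likelihood underflow")
            L[v] = vec / m
            log_scale += math.log(m)
    return L, log_scale, P


def mk_loglik(tree: Tree, data: Mapping[str, str], model: MkModel) -> float:
    """Pruning (postorder) log-likelihood of the tip states under ``model``."""
    L, log_scale, _ = _partials(tree, data, model)
    lik = float(model.root_prior @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return math.log(lik) + log_scale


@dataclass
class MkFit:
    """Result of ML rate estimation for an Mk model."""

    model: MkModel
    loglik: float
    at_lower_bound: bool = False
    converged: bool = True

    @property
    def rate(self) -> float:
        """The single ER rate (first off-diagonal entry)."""
        return float(self.model.Q[0, 1])


def fit_mk(
    tree: Tree,
    data: Mapping[str, str],
    structure: str = "ER",
    states: Sequence[str] = HABITAT_STATES,
    root_prior: np.ndarray | None = None,
) -> MkFit:
    """Maximize the Mk likelihood over transition rates.

    Optimization is on the log-rate scale, bounded in
    ``[RATE_LO, RATE_HI]`` transitions per unit tree depth.  Monomorphic data
    drive the rate to the lower bound; this is flagged, not an error.
    """
    observed = {data[lab] for lab in tree.labels if lab in data}
    _tip_state_indices(tree, data, states)  # raise early on missing tips
    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def er_negll(logr: float) -> float:
        return -mk_loglik(tree, data, er_model(math.exp(logr), states, root_prior))

    res = minimize_scalar(er_negll, bounds=(lo, hi), method="bounded")
    er_rate = math.exp(res.x)
    if structure == "ER":
        model = er_model(er_rate, states, root_prior)
        return MkFit(
            model,
            -float(res.fun),
            at_lower_bound=res.x < lo + 1e-3 or len(observed) < 2,
            converged=bool(res.success),
        )
    if structure != "ARD":
        raise ValueError(f"unknown Mk structure {structure!r}")
    k = len(states)
    n_off = k * (k - 1)
    mask = ~np.eye(k, dtype=bool)

    def ard_negll(logr: np.ndarray) -> float:
        R = np.zeros((k, k))
        R[mask] = np.exp(logr)
        return -mk_loglik(tree, data, ard_model(R, states, root_prior))

    x0 = np.full(n_off, math.log(max(er_rate, RATE_LO * 10)))
    opt = minimize(
        ard_negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * n_off,
        options={"maxiter": 500},
    )
    R = np.zeros((k, k))
    R[mask] = np.exp(opt.x)
    return MkFit(
        ard_model(R, states, root_prior),
        -float(opt.fun),
        at_lower_bound=bool(np.any(opt.x < lo + 1e-3)),
        converged=bool(opt.success),
    )


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling
# ---------------------------------------------------------------------------


def _forward_path(Q: np.ndarray, i: int, t: float, rng: np.random.Generator):
    """Unconditioned CTMC path from state ``i`` over duration ``t``."""
    path = [(i, 0.0)]
    s, elapsed = i, 0.0
    while True:
        out_rate = -Q[s, s]
        if out_rate <= 0:
            break
        wait = rng.exponential(1.0 / out_rate)
        if elapsed + wait >= t:
            break
        elapsed += wait
        probs = Q[s].clip(min=0.0)
        probs[s] = 0.0
        s = int(rng.choice(len(probs), p=probs / probs.sum()))
        path.append((s, elapsed))
    segs = []
    for m, (state, start) in enumerate(path):
        end = path[m + 1][1] if m + 1 < len(path) else t
        segs.append((state, end - start))
    return segs, s


def _uniformized_path(
    Q: np.ndarray, i: int, j: int, t: float, Pt_ij: float, rng: np.random.Generator
):
    """Endpoint-conditioned path via uniformization (always terminates)."""
    k = Q.shape[0]
    mu = float(-Q.diagonal().min())
    if mu <= 0:
        return [(i, t)]
    R = np.eye(k) + Q / mu
    # sample the number of (possibly virtual) jumps
    target = rng.uniform() * Pt_ij
    powers = [np.eye(k)]
    log_pois = -mu * t
    cum = 0.0
    n = 0
    while True:
        cum += math.exp(log_pois) * powers[n][i, j]
        if cum >= target and powers[n][i, j] > 0 and (n > 0 or i == j):
            break
        n += 1
        powers.append(powers[-1] @ R)
        log_pois += math.log(mu * t) - math.log(n)
        if n > 100_000:  # pragma: no cover - unreachable safeguard
            break
    if n == 0:
        return [(i, t)]
    # jump chain bridge: states s_0=i .. s_n=j
    states = [i]
    for m in range(1, n):
        w = R[states[-1]] * powers[n - m][:, j]
        states.append(int(rng.choice(k, p=w / w.sum())))
    states.append(j)
    times = np.sort(rng.uniform(0.0, t, size=n))
    segs = []
    prev_t = 0.0
    for m in range(n):
        segs.append((states[m], float(times[m]) - prev_t))
        prev_t = float(times[m])
    segs.append((states[n], t - prev_t))
    return segs


def _conditioned_path(
    Q: np.ndarray,
    i: int,
    j: int,
    t: float,
    Pt_ij: float,
    rng: np.random.Generator,
    max_reject: int = MAX_REJECTIONS,
):
    """Sample a CTMC path on ``[0, t]`` conditioned on the endpoint states."""
    if t <= 0:
        return [(i, 0.0)] if i == j else [(i, 0.0), (j, 0.0)]
    for _ in range(max_reject):
        segs, end = _forward_path(Q, i, t, rng)
        if end == j:
            return segs
    return _uniformized_path(Q, i, j, t, Pt_ij, rng)


def sample_maps(
    tree: Tree,
    data: Mapping[str, str],
    model: MkModel,
    n_maps: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[StochasticMap]:
    """Draw stochastic character maps conditioned on the observed tip states.

    Each map is sampled by (1) a pruning pass for conditional likelihoods,
    (2) drawing the root state from its marginal posterior, (3) a preorder
    pass drawing each node's state given its parent's state and the data
    below it, and (4) endpoint-conditioned path simulation along every
    branch.  The pruning pass is shared across all ``n_maps`` draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, _, P = _partials(tree, data, model)
    k = model.n_states
    root = tree.root
    root_w = model.root_prior * L[root]
    if root_w.sum() <= 0:
        raise ValueError("data have zero likelihood under this model")
    root_p = root_w / root_w.sum()
    maps = []
    for _ in range(int(n_maps)):
        node_state = np.empty(tree.n_nodes, dtype=np.intp)
        node_state[root] = rng.choice(k, p=root_p)
        segments: list[list[tuple[str, float]]] = [[] for _ in range(tree.n_nodes)]
        for v in tree.preorder:
            if v == root:
                continue
            i = int(node_state[tree.parent[v]])
            w = P[v][i] * L[v]
            w_sum = w.sum()
            if w_sum <= 0:  # numerically dead branch; fall back to parent state
                j = i
            else:
                j = int(rng.choice(k, p=w / w_sum))
            node_state[v] = j
            path = _conditioned_path(model.Q, i, j, float(tree.blen[v]), float(P[v][i, j]), rng)
            segments[v] = [(model.states[s], d) for s, d in path]
        maps.append(StochasticMap(tree, segments))
    return maps


# ---------------------------------------------------------------------------
# Origin counting
# ---------------------------------------------------------------------------


def count_origins(
    smap: StochasticMap, states: Sequence[str] = HABITAT_STATES
) -> dict[str, int]:
    """Independent origins of each state on one map.

    An origin of state ``s`` is a transition *into* ``s`` anywhere on the
    tree, plus one if the root itself starts in ``s``.
    """
    counts = {s: 0 for s in states}
    counts[smap.root_state] = counts.get(smap.root_state, 0) + 1
    for segs in smap.segments:
        for (prev, _), (cur, _) in zip(segs, segs[1:]):
            if cur != prev and cur in counts:
                counts[cur] += 1
    return counts


def origin_summary(
    maps: Sequence[StochasticMap], states: Sequence[str] = HABITAT_STATES
):
    """Median/min/max origin counts per state over an ensemble of maps."""
    import pandas as pd

    counts = {s: [] for s in states}
    for m in maps:
        c = count_origins(m, states)
        for s in states:
            counts[s].append(c[s])
    return pd.DataFrame(
        {
            "state": list(states),
            "median": [float(np.median(counts[s])) for s in states],
            "min": [int(np.min(counts[s])) for s in states],
            "max": [int(np.max(counts[s])) for s in states],
            "frac_multiple": [float(np.mean(np.array(counts[s]) > 1)) for s in states],
        }
    )
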