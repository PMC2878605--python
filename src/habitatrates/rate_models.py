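"""Multi-rate Brownian motion models over stochastic character maps.

Each candidate model partitions the four habitat states into rate classes and
assigns one Brownian rate (σ², trait variance per unit relative time) to each
class.  Under a given stochastic map the expected covariance of species trait
values is

    V = Σ_k σ²_class(k) · S_k + diag(sampling variances),

where ``S_k`` holds, for every pair of tips, the time their shared
root-to-tip path spends in habitat state ``k`` (the noncensored likelihood:
branches contribute in proportion to their state occupancy, the tree is never
split).  The likelihood is multivariate normal with a common ancestral mean;
the mean is profiled out analytically as the GLS estimate, and the per-class
rates are optimized on the log scale with an analytic gradient.

Model comparison uses AICc with ``n`` = number of species and
``k`` = number of rate classes + 1 (the estimated root state); Akaike weights
and per-habitat model-averaged rates follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .tree_model import HABITAT_STATES, StochasticMap

#: Bounds for the per-class rate optimization (σ², trait² per unit depth).
SIGMA2_LO = 1e-10
SIGMA2_HI = 1e6

#: Relative diagonal jitter applied before Cholesky factorization.
JITTER = 1e-10

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RateModelSpec:
    """A partition of the habitat states into Brownian rate classes."""

    name: str
    partition: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, name: str, partition: Mapping[str, int]) -> "RateModelSpec":
        return cls(name, tuple(sorted(partition.items())))

    @property
    def mapping(self) -> dict[str, int]:
        return dict(self.partition)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.partition)

    @property
    def n_classes(self) -> int:
        return len({c for _, c in self.partition})

    @property
    def k(self) -> int:
        """Free parameters: one rate per class plus the root state."""
        return self.n_classes + 1

    def class_of(self, state: str) -> int:
        return self.mapping[state]

    def __post_init__(self):
        classes = sorted({c for _, c in self.partition})
        if classes != list(range(len(classes))):
            raise ValueError("class indices must be 0..n_classes-1")


def build_model_set(states: Sequence[str] = HABITAT_STATES) -> list[RateModelSpec]:
    """The ten candidate habitat-partition models.

    One four-rate model, three three-rate models merging states with
    hypothesized shared effects, four two-rate models isolating one state,
    one two-rate model contrasting steeply inclined surfaces (rock, arboreal)
    with ground use (terrestrial, semi-arboreal), and the single-rate model.
    """
    rock, terr, semi, arb = states

    def spec(name: str, groups: Sequence[Sequence[str]]) -> RateModelSpec:
        part = {s: c for c, grp in enumerate(groups) for s in grp}
        return RateModelSpec.from_mapping(name, part)

    return [
        spec("4-rate full", [[rock], [terr], [semi], [arb]]),
        spec("3-rate shared tree effect", [[rock], [terr], [semi, arb]]),
        spec("3-rate shared ground effect", [[rock], [terr, semi], [arb]]),
        spec("3-rate shared incline effect", [[rock, arb], [terr], [semi]]),
        spec("2-rate rock effect", [[rock], [terr, semi, arb]]),
        spec("2-rate terrestrial effect", [[terr], [rock, semi, arb]]),
        spec("2-rate semi-arboreal effect", [[semi], [rock, terr, arb]]),
        spec("2-rate arboreal effect", [[arb], [rock, terr, semi]]),
        spec("2-rate incline-ground", [[rock, arb], [terr, semi]]),
        spec("1-rate no effect", [[rock, terr, semi, arb]]),
    ]


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _align(values, labels: Sequence[str], what: str) -> np.ndarray:
    if isinstance(values, pd.Series):
        missing = set(labels) - set(values.index)
        if missing:
            raise KeyError(f"{what} missing for species: {sorted(missing)}")
        return values.reindex(list(labels)).to_numpy(dtype=float)
    if isinstance(values, Mapping):
        missing = set(labels) - set(values)
        if missing:
            raise KeyError(f"{what} missing for species: {sorted(missing)}")
        return np.array([float(values[lab]) for lab in labels])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(labels),):
        raise ValueError(f"{what} must have one value per tip")
    return arr


class BMLikelihood:
    """Profile likelihood for one map × one trait axis, reusable across models.

    Precomputes the per-state shared-path stack once; each candidate model
    only re-aggregates it into per-class matrices.
    """

    def __init__(
        self,
        smap: StochasticMap | None,
        traits,
        sampling_vars=None,
        states: Sequence[str] = HABITAT_STATES,
        stack: np.ndarray | None = None,
        labels: Sequence[str] | None = None,
    ):
        self.smap = smap
        self.states = tuple(states)
        if smap is not None:
            labels = smap.tree.labels
        elif stack is None or labels is None:
            raise ValueError("provide either a map or a precomputed stack + labels")
        labels = tuple(labels)
        self.labels = labels
        self.x = _align(traits, labels, "trait values")
        if sampling_vars is None:
            self.sv = np.zeros(len(labels))
        else:
            self.sv = _align(sampling_vars, labels, "sampling variances")
        if np.any(self.sv < 0):
            raise ValueError("sampling variances must be nonnegative")
        self.S = stack if stack is not None else smap.shared_path_stack(self.states)
        self.n = len(labels)

    def class_matrices(self, model: RateModelSpec) -> np.ndarray:
        """Aggregate the state stack into per-rate-class matrices ``A_c``."""
        c = model.n_classes
        A = np.zeros((c, self.n, self.n))
        for k, s in enumerate(self.states):
            A[model.class_of(s)] += self.S[k]
        return A

    def vcv(self, model: RateModelSpec, rates) -> np.ndarray:
        """Expected trait covariance ``Σ_c σ²_c A_c + diag(sampling vars)``."""
        A = self.class_matrices(model)
        theta = np.asarray(rates, dtype=float)
        if theta.shape != (model.n_classes,):
            raise ValueError(
                f"expected {model.n_classes} rates for {model.name!r}, got {theta.shape}"
            )
        if np.any(theta < 0):
            raise ValueError("rates must be nonnegative")
        return np.tensordot(theta, A, axes=1) + np.diag(self.sv)

    @staticmethod
    def _chol(V: np.ndarray):
        d = float(np.trace(V)) / len(V)
        for jit in (0.0, JITTER, 1e4 * JITTER):
            try:
                if jit == 0.0:
                    return cho_factor(V, lower=True)
                return cho_factor(V + jit * d * np.eye(len(V)), lower=True)
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError(
            "trait covariance matrix is singular; consider a sampling-variance floor"
        )

    def _profile_parts(self, A: np.ndarray, theta: np.ndarray):
        V = np.tensordot(theta, A, axes=1)
        V[np.diag_indices(self.n)] += self.sv
        cf = self._chol(V)
        rhs = np.column_stack([np.ones(self.n), self.x])
        sol = cho_solve(cf, rhs)
        mu = float(sol[:, 1].sum()) / float(sol[:, 0].sum())
        u = sol[:, 1] - mu * sol[:, 0]
        r = self.x - mu
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (float(r @ u) + logdet + self.n * LOG2PI)
        return ll, mu, u, cf

    def profile_loglik(self, model: RateModelSpec, rates) -> tuple[float, float]:
        """(log-likelihood, GLS root state) with the mean profiled out."""
        A = self.class_matrices(model)
        theta = np.asarray(rates, dtype=float)
        ll, mu, _, _ = self._profile_parts(A, theta)
        return ll, mu

    def loglik(self, model: RateModelSpec, rates, root: float) -> float:
        """Log-likelihood at a fixed ancestral mean ``root``."""
        V = self.vcv(model, rates)
        cf = self._chol(V)
        r = self.x - float(root)
        u = cho_solve(cf, r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return -0.5 * (float(r @ u) + logdet + self.n * LOG2PI)

    # -- optimization ------------------------------------------------------

    def _neg_profile_and_grad(self, A: np.ndarray, phi: np.ndarray):
        theta = np.exp(phi)
        ll, _, u, cf = self._profile_parts(A, theta)
        Vi = cho_solve(cf, np.eye(self.n))
        tr = np.einsum("ij,cij->c", Vi, A)
        quad = np.einsum("i,cij,j->c", u, A, u)
        return -ll, 0.5 * (tr - quad) * theta

    def _starts(
        self, model: RateModelSpec, start_rate: float, extra, fan: bool = True
    ) -> list[np.ndarray]:
        """Start points for the rate optimization.

        The profile likelihood in the per-class rates can be multimodal
        (basins where one class absorbs the variance the data assign to
        another), and uniform rescalings of the single-rate estimate all sit
        in the same basin.  The start fan therefore combines the uniform
        single-rate start with its ×0.1/×10 rescalings and, for every class,
        an asymmetric start in which that class is fast (×10) and the rest
        slow (×0.1).  Callers may append extra starts (e.g. the full-model
        optimum collapsed onto a restricted model's classes).
        """
        c = model.n_classes
        base = min(max(start_rate, SIGMA2_LO * 10), SIGMA2_HI / 10)
        starts = [np.full(c, base)]
        if fan:
            starts += [np.full(c, 0.1 * base), np.full(c, 10 * base)]
            for j in range(c):
                axis = np.full(c, 0.1 * base)
                axis[j] = 10 * base
                starts.append(axis)
        for theta in extra or ():
            starts.append(np.clip(np.asarray(theta, dtype=float), SIGMA2_LO, SIGMA2_HI))
        return starts

    def fit(
        self,
        model: RateModelSpec,
        start_rate: float | None = None,
        extra_starts=None,
        fan: bool = True,
    ) -> "FitResult":
        """ML rates for one model; the root state is profiled analytically.

        ``start_rate`` seeds the start fan (typically the single-rate ML
        estimate; computed internally when omitted); all starts are run and
        the best optimum kept.  With ``fan=False`` only the uniform start and
        any ``extra_starts`` are used — appropriate when a caller supplies a
        well-informed seed such as the collapsed optimum of a richer nested
        model.  The single-rate model itself is fitted by bounded scalar
        optimization.
        """
        A = self.class_matrices(model)
        lo, hi = math.log(SIGMA2_LO), math.log(SIGMA2_HI)
        if model.n_classes == 1:
            res = minimize_scalar(
                lambda phi: self._neg_profile_and_grad(A, np.array([phi]))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-9},
            )
            phi_best, nll_best, ok = np.array([res.x]), float(res.fun), bool(res.success)
        else:
            if start_rate is None:
                one_rate = RateModelSpec.from_mapping(
                    "1-rate", {s: 0 for s in self.states}
                )
                start_rate = self.fit(one_rate).rates[0]
            phi_best, nll_best, ok = None, np.inf, False
            for theta0 in self._starts(model, start_rate, extra_starts, fan):
                phi0 = np.clip(np.log(theta0), lo, hi)
                opt = minimize(
                    lambda p: self._neg_profile_and_grad(A, p),
                    phi0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(lo, hi)] * model.n_classes,
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
                )
                if float(opt.fun) < nll_best - 1e-12 or phi_best is None:
                    phi_best, nll_best, ok = opt.x, float(opt.fun), bool(opt.success)
        theta = np.exp(phi_best)
        ll, mu = self.profile_loglik(model, theta)
        return FitResult(
            model=model,
            rates=theta,
            root=mu,
            loglik=ll,
            n=self.n,
            # AICc is undefined for very small species subsets (clade fits);
            # the rates/loglik remain valid, so flag with NaN rather than fail
            aicc_score=(
                aicc(ll, model.k, self.n) if self.n > model.k + 1 else math.nan
            ),
            converged=ok,
            at_bound=bool(np.any(phi_best < lo + 1e-6) or np.any(phi_best > hi - 1e-6)),
        )


@dataclass
class FitResult:
    """ML fit of one rate model on one reconstruction."""

    model: RateModelSpec
    rates: np.ndarray
    root: float
    loglik: float
    n: int
    aicc_score: float
    converged: bool = True
    at_bound: bool = False

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def name(self) -> str:
        return self.model.name

    def rate_for(self, habitat: str) -> float:
        """The fitted σ² of the class containing ``habitat``."""
        return float(self.rates[self.model.class_of(habitat)])

    def habitat_rates(self, states: Sequence[str] = HABITAT_STATES) -> pd.Series:
        return pd.Series({s: self.rate_for(s) for s in states})


# ---------------------------------------------------------------------------
# Convenience functional surface
# ---------------------------------------------------------------------------


def expected_vcv(
    smap: StochasticMap,
    model: RateModelSpec,
    rates,
    sampling_vars=None,
    states: Sequence[str] = HABITAT_STATES,
) -> np.ndarray:
    """Expected species trait covariance under a map, model and rates."""
    zeros = np.zeros(smap.tree.n_tips)
    lik = BMLikelihood(smap, zeros, sampling_vars, states)
    return lik.vcv(model, rates)


def bm_loglik(
    smap: StochasticMap,
    model: RateModelSpec,
    rates,
    root: float | None,
    traits,
    sampling_vars=None,
    states: Sequence[str] = HABITAT_STATES,
) -> float:
    """Multivariate-normal Brownian log-likelihood.

    With ``root=None`` the ancestral mean is profiled out (GLS estimate);
    otherwise the likelihood is evaluated at the given root value.
    """
    lik = BMLikelihood(smap, traits, sampling_vars, states)
    if root is None:
        return lik.profile_loglik(model, rates)[0]
    return lik.loglik(model, rates, root)


def fit_model(
    smap: StochasticMap,
    model: RateModelSpec,
    traits,
    sampling_vars=None,
    states: Sequence[str] = HABITAT_STATES,
    start_rate: float | None = None,
) -> FitResult:
    """Fit one model on one reconstruction (see :meth:`BMLikelihood.fit`)."""
    lik = BMLikelihood(smap, traits, sampling_vars, states)
    return lik.fit(model, start_rate=start_rate)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = 2k − 2lnL + 2k(k+1)/(n−k−1); requires ``n > k + 1``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from a list of AICc scores."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be a nonempty finite list")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def model_average_rates(
    fits: Sequence[FitResult],
    weights,
    states: Sequence[str] = HABITAT_STATES,
) -> pd.Series:
    """Per-habitat model-averaged rate: ``Σ_m w_m σ²_m(habitat)``."""
    w = np.asarray(weights, dtype=float)
    if len(fits) != len(w):
        raise ValueError(f"{len(fits)} fits but {len(w)} weights")
    out = pd.Series(0.0, index=list(states))
    for fit, wm in zip(fits, w):
        for s in states:
            out[s] += wm * fit.rate_for(s)
    return out
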