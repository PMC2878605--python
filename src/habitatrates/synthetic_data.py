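"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study design end to end: an ensemble of
ultrametric trees standing in for a posterior sample (Yule trees with
log-normal branch-length jitter, re-ultrametrized to root depth 1.0), a
four-state habitat character evolving by a continuous-time Markov process,
continuous traits evolving by habitat-dependent-rate Brownian motion, and
within-species measurement replicates with the empirical 1–36 (median 4)
individuals-per-species profile.

The Yule simulator is written directly (exponential waiting times with rate
``k·λ`` while ``k`` lineages are extant, stopping one holding time after the
``n``-th birth) so that its inter-node interval distribution is exactly the
pure-birth order statistic — the property the test suite verifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .habitat_mapping import MkModel, _forward_path, er_model
from .rate_models import RateModelSpec, build_model_set
from .tree_model import HABITAT_STATES, StochasticMap, Tree


@dataclass
class SimConfig:
    """Generating parameters for a full synthetic study.

    Defaults mirror the analysis design this package targets: 90 species,
    trees rescaled to root depth 1.0, 500 reconstructions (50 jittered trees
    × 10 stochastic maps each), four habitat states with roughly 15–20
    transitions per history, strongly habitat-structured Brownian rates
    spanning two orders of magnitude, and 1–36 (median 4) individuals per
    species.
    """

    n_tips: int = 90
    birth_rate: float = 1.0
    n_trees: int = 50
    maps_per_tree: int = 10
    perturb_sd: float = 0.05
    mk_rate: float = 0.6
    states: tuple[str, ...] = HABITAT_STATES
    bm_rates: tuple[float, ...] = (1.0, 25.0, 125.0, 5.0)  # per states order
    root_value: float = 0.0
    within_sd: float = 0.1
    individuals_lo: int = 1
    individuals_hi: int = 36
    individuals_median: int = 4
    seed: int = 0

    @property
    def n_reconstructions(self) -> int:
        return self.n_trees * self.maps_per_tree

    def rates_by_state(self) -> dict[str, float]:
        return dict(zip(self.states, self.bm_rates))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(
    n_tips: int,
    seed=None,
    birth_rate: float = 1.0,
    rescale: bool = True,
    label_prefix: str = "sp",
) -> Tree:
    """Pure-birth (Yule) tree, by default rescaled to root depth 1.0.

    The process starts from two lineages at the root; while ``k`` lineages
    are extant the next split arrives after an ``Exp(k·λ)`` wait on a
    uniformly chosen lineage, and the tips extend one further ``Exp(n·λ)``
    holding time after the last split.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = _as_rng(seed)
    # active lineages as (parent_node_id, start_time); nodes created on split
    parent: list[int] = [-1]
    start: list[float] = [0.0]
    blen: list[float] = [0.0]
    active: list[int] = [0]
    t = 0.0
    # root immediately splits into two lineages
    for _ in range(2):
        parent.append(0)
        start.append(0.0)
        blen.append(0.0)
        active.append(len(parent) - 1)
    active.pop(0)
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active.pop(i)
        blen[node] = t - start[node]
        for _ in range(2):
            parent.append(node)
            start.append(t)
            blen.append(0.0)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        blen[node] = t - start[node]
    # renumber: tips first (in creation order), then internals, root last
    is_tip = [i in set(active) for i in range(len(parent))]
    tip_old = [i for i, b in enumerate(is_tip) if b]
    int_old = [i for i, b in enumerate(is_tip) if not b]
    new = {old: i for i, old in enumerate(tip_old)}
    new.update({old: len(tip_old) + i for i, old in enumerate(int_old)})
    n = len(parent)
    parent_arr = np.full(n, -1, dtype=np.intp)
    blen_arr = np.zeros(n)
    for old in range(n):
        if parent[old] >= 0:
            parent_arr[new[old]] = new[parent[old]]
        blen_arr[new[old]] = blen[old]
    width = len(str(n_tips))
    labels = [f"{label_prefix}{i + 1:0{width}d}" for i in range(n_tips)]
    tree = Tree(parent_arr, blen_arr, labels)
    return tree.rescaled(1.0) if rescale else tree


def perturb_tree_ensemble(
    tree: Tree, R: int, sd: float, seed=None
) -> list[Tree]:
    """Stand-in for posterior tree uncertainty: branch-length jitter.

    Each branch length is multiplied by an independent log-normal factor with
    mean 1 and coefficient of variation ``sd``; terminal branches are then
    stretched so every tip reaches the deepest tip, and the tree is rescaled
    to root depth 1.0.  ``sd = 0`` returns ``R`` copies of the input.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = _as_rng(seed)
    if sd == 0:
        return [Tree(tree.parent, tree.blen, tree.labels) for _ in range(R)]
    sigma = np.sqrt(np.log1p(sd**2))
    out = []
    for _ in range(int(R)):
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=tree.n_nodes)
        blen = tree.blen * factors
        blen[tree.root] = 0.0
        jittered = Tree(tree.parent, blen, tree.labels, check_ultrametric=False)
        d = jittered.depths()
        target = d[: tree.n_tips].max()
        for tip in range(tree.n_tips):
            blen[tip] += target - d[tip]
        out.append(Tree(tree.parent, blen, tree.labels).rescaled(1.0))
    return out


def simulate_mk_history(
    tree: Tree, model: MkModel, root_state: str | None = None, seed=None
) -> tuple[StochasticMap, dict[str, str]]:
    """Forward-simulate a discrete character history down the tree.

    Returns the realized stochastic map and the tip states it implies.  With
    ``root_state=None`` the root is drawn from the model's root prior.
    """
    rng = _as_rng(seed)
    if root_state is None:
        root_idx = int(rng.choice(model.n_states, p=model.root_prior))
    else:
        root_idx = model.states.index(root_state)
    node_state = np.empty(tree.n_nodes, dtype=np.intp)
    node_state[tree.root] = root_idx
    segments: list[list[tuple[str, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        if v == tree.root:
            continue
        i = int(node_state[tree.parent[v]])
        path, end = _forward_path(model.Q, i, float(tree.blen[v]), rng)
        node_state[v] = end
        segments[v] = [(model.states[s], d) for s, d in path]
    smap = StochasticMap(tree, segments)
    return smap, smap.tip_states()


def simulate_multirate_bm(
    smap: StochasticMap,
    model: RateModelSpec,
    rates,
    root: float = 0.0,
    seed=None,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Brownian tip values under per-habitat-class rates along a map.

    Along each branch the trait change is Gaussian with variance
    ``Σ_segments σ²_state × duration`` (exact under Brownian motion, since
    within-branch increments are independent).  Returns a species × replicate
    table; column ``rep0`` is the first replicate.
    """
    rng = _as_rng(seed)
    theta = np.asarray(rates, dtype=float)
    if np.any(theta < 0):
        raise ValueError("rates must be nonnegative")
    tree = smap.tree
    var = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        var[v] = sum(theta[model.class_of(s)] * d for s, d in smap.segments[v])
    vals = np.zeros((tree.n_nodes, int(n_reps)))
    vals[tree.root] = root
    for v in tree.preorder:
        if v == tree.root:
            continue
        step = rng.normal(0.0, np.sqrt(var[v]), size=int(n_reps)) if var[v] > 0 else 0.0
        vals[v] = vals[tree.parent[v]] + step
    return pd.DataFrame(
        vals[: tree.n_tips],
        index=list(tree.labels),
        columns=[f"rep{i}" for i in range(int(n_reps))],
    )


def draw_individual_counts(
    n_species: int,
    seed=None,
    lo: int = 1,
    hi: int = 36,
    median: int = 4,
) -> np.ndarray:
    """Per-species individual counts from a truncated geometric distribution.

    The geometric success probability is tuned so the population median is
    exactly ``median`` (``p = 1 − 0.5^(1/(median − ½))`` puts strictly more
    than half the mass at or below ``median`` and strictly less below it),
    then counts are clipped to ``[lo, hi]``.
    """
    rng = _as_rng(seed)
    p = 1.0 - 0.5 ** (1.0 / (median - 0.5))
    counts = rng.geometric(p, size=int(n_species))
    return np.clip(counts, lo, hi)


def simulate_individuals(
    species_values: pd.DataFrame | pd.Series,
    n_per_species,
    within_sd: float,
    seed=None,
    species_col: str = "species",
) -> pd.DataFrame:
    """Individual-level replicates around species values.

    ``species_values`` is a species × variable table (a Series is treated as
    one variable named ``trait``); each individual's value per variable is
    ``Normal(species value, within_sd²)``.
    """
    rng = _as_rng(seed)
    if isinstance(species_values, pd.Series):
        species_values = species_values.to_frame("trait")
    if isinstance(n_per_species, Mapping) or isinstance(n_per_species, pd.Series):
        counts = [int(n_per_species[s]) for s in species_values.index]
    else:
        counts = [int(x) for x in np.broadcast_to(n_per_species, len(species_values))]
    if min(counts) < 1:
        raise ValueError("each species needs at least one individual")
    rows = []
    for (species, vals), n in zip(species_values.iterrows(), counts):
        base = vals.to_numpy(dtype=float)
        noise = rng.normal(0.0, within_sd, size=(n, len(base)))
        for i in range(n):
            rows.append(
                {species_col: species, "individual_id": f"{species}_{i + 1}", **dict(zip(species_values.columns, base + noise[i]))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study generator
# ---------------------------------------------------------------------------

#: Per-axis Brownian rates by habitat class, loosely matching the magnitude
#: profile of a strongly habitat-structured radiation: one dominant size-like
#: axis and three progressively quieter shape-like axes.  Order follows
#: :data:`HABITAT_STATES` (rock, terrestrial, semiarboreal, arboreal).
DEFAULT_AXIS_RATES: tuple[tuple[float, ...], ...] = (
    (2.0, 20.0, 145.0, 13.0),
    (0.07, 1.5, 0.3, 0.5),
    (0.03, 1.9, 0.8, 0.4),
    (0.01, 0.5, 0.5, 0.24),
)


def _measurement_loadings(n_vars: int = 13, n_axes: int = 4) -> np.ndarray:
    """Fixed variables × axes mixing matrix with a dominant size column.

    Column 1 is the uniform size direction; the shape columns are smooth
    orthonormalized contrasts, so a correlation-matrix PCA of data generated
    through this matrix recovers one dominant component plus minor axes.
    """
    i = np.arange(n_vars)
    raw = np.column_stack(
        [np.ones(n_vars)]
        + [np.cos((j + 1) * np.pi * (i + 0.5) / n_vars) for j in range(n_axes - 1)]
    )
    q, _ = np.linalg.qr(raw)
    return q * np.sign(q[0])


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> dict:
    """Generate a complete synthetic study matching ``config``.

    Returns a dict with the reference tree and habitat history, the
    reconstruction ensemble (``n_trees × maps_per_tree`` stochastic maps
    drawn under refitted trees), the habitat table, latent trait axes, an
    individuals-by-measurements table (13 log-scale variables mixed from the
    latent axes), and the generating parameters.
    """
    from .habitat_mapping import fit_mk, sample_maps

    cfg = config or SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    root_seed = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in root_seed.spawn(6)]

    true_tree = simulate_yule_tree(cfg.n_tips, rngs[0], cfg.birth_rate)
    mk = er_model(cfg.mk_rate, cfg.states)
    # resimulate until every state is observed at the tips, so all four
    # habitat classes are identifiable downstream
    for _ in range(200):
        true_map, habitat = simulate_mk_history(true_tree, mk, seed=rngs[1])
        if set(habitat.values()) == set(cfg.states):
            break
    else:
        raise RuntimeError("could not realize all habitat states; raise mk_rate")

    axes_scores = {}
    spec4 = build_model_set(cfg.states)[0]
    rate_table = [cfg.bm_rates] + [r for r in DEFAULT_AXIS_RATES[1:]]
    rate_table = rate_table[:4]
    for a, rates in enumerate(rate_table):
        vals = simulate_multirate_bm(
            true_map, spec4, rates, cfg.root_value, rngs[2]
        )["rep0"]
        axes_scores[f"axis{a + 1}"] = vals
    axes_df = pd.DataFrame(axes_scores)

    L = _measurement_loadings(13, 4)
    # latent-axis units → log-mm, sized so the across-species size spread
    # (≈0.5 log units per variable) dominates the within-species noise, giving
    # the dominant first principal component typical of linear morphometrics
    scale = 0.25
    log_means = pd.DataFrame(
        4.0 + scale * axes_df.to_numpy() @ L.T,
        index=axes_df.index,
        columns=[f"m{j + 1:02d}" for j in range(13)],
    )
    counts = draw_individual_counts(
        cfg.n_tips, rngs[3], cfg.individuals_lo, cfg.individuals_hi, cfg.individuals_median
    )
    measurements = simulate_individuals(
        log_means, pd.Series(counts, index=log_means.index), cfg.within_sd, rngs[3]
    )

    trees = perturb_tree_ensemble(true_tree, cfg.n_trees, cfg.perturb_sd, rngs[4])
    maps: list[StochasticMap] = []
    for tree in trees:
        refit = fit_mk(tree, habitat, structure="ER", states=cfg.states)
        maps.extend(
            sample_maps(tree, habitat, refit.model, cfg.maps_per_tree, rngs[5])
        )

    return {
        "config": cfg,
        "true_tree": true_tree,
        "true_map": true_map,
        "habitat": habitat,
        "axes": axes_df,
        "measurement_loadings": L,
        "measurements": measurements,
        "trees": trees,
        "maps": maps,
    }


def write_dataset(dataset: dict, outdir: str) -> None:
    """Write a simulated study to disk (trees, maps, habitat CSV,
    measurements CSV, ground-truth JSON)."""
    import os

    from .tree_model import write_maps, write_trees

    os.makedirs(outdir, exist_ok=True)
    cfg: SimConfig = dataset["config"]
    write_trees(dataset["trees"], os.path.join(outdir, "trees.nwk"))
    write_maps(dataset["maps"], os.path.join(outdir, "maps.simmap"))
    pd.Series(dataset["habitat"], name="habitat").rename_axis("species").to_csv(
        os.path.join(outdir, "habitat.csv")
    )
    meas = dataset["measurements"].copy()
    value_cols = [c for c in meas.columns if c not in ("species", "individual_id")]
    meas[value_cols] = np.exp(meas[value_cols])  # CSV holds raw mm
    meas.to_csv(os.path.join(outdir, "measurements.csv"), index=False)
    truth = {
        "seed": cfg.seed,
        "n_tips": cfg.n_tips,
        "n_trees": cfg.n_trees,
        "maps_per_tree": cfg.maps_per_tree,
        "perturb_sd": cfg.perturb_sd,
        "mk_rate": cfg.mk_rate,
        "states": list(cfg.states),
        "bm_rates": list(cfg.bm_rates),
        "root_value": cfg.root_value,
        "within_sd": cfg.within_sd,
        "true_tree": dataset["true_tree"].to_newick(),
        "true_map": dataset["true_map"].to_simmap(),
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
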