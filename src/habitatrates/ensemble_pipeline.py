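"""Ensemble model fitting over many habitat reconstructions, plus reporting.

Every candidate rate model is fitted to every trait axis on every stochastic
map in the ensemble.  Because the species data are identical across
reconstructions, AICc may be averaged across the ensemble and compared
between models; per-reconstruction ΔAICc distributions describe the
sensitivity of model choice to reconstruction uncertainty.

Summary conventions
-------------------
* The ``±`` spread reported for parameters and fit scores is, by default,
  the standard deviation of the per-reconstruction values — it describes
  reconstruction uncertainty, not the Monte-Carlo error of the mean.  Set
  ``se_mode="sem"`` for sd/√R.
* The headline ΔAICc and Akaike-weight columns are computed from the mean
  AICc across reconstructions.
* Per reconstruction, the *preferred* model is the AICc minimum (ties go to
  the smaller parameter count) and a model is *disfavoured* when its ΔAICc
  exceeds 2.0.
* Model-averaged per-habitat rates are computed within each reconstruction
  (weights from that reconstruction's AICc) and then summarized across the
  ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rate_models import (
    HABITAT_STATES,
    BMLikelihood,
    RateModelSpec,
    akaike_weights,
    build_model_set,
)
from .tree_model import StochasticMap

logger = logging.getLogger(__name__)

#: ΔAICc beyond which a model counts as disfavoured on a reconstruction.
DISFAVOURED_DELTA = 2.0


def _axis_columns(trait_table: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs of (score column, sampling-variance column) in the trait table."""
    axes = []
    for c in trait_table.columns:
        if c.startswith("pc") and c[2:].isdigit():
            var = "var" + c[2:]
            axes.append((c, var if var in trait_table.columns else None))
    if not axes:
        raise ValueError("trait table has no pc1..pcK columns")
    return axes


@dataclass
class EnsembleSummary:
    """Model-comparison surfaces for one ensemble run.

    Attributes
    ----------
    fits
        Per trait axis, a models × statistics table: mean and spread of each
        per-habitat rate, root state, −lnL and AICc, plus ΔAICc and Akaike
        weight computed from the mean AICc.
    support
        Per trait axis, the per-reconstruction ΔAICc summary per model:
        mid-95% interval, percent preferred and percent disfavoured.
    averaged_rates
        Habitat × axis table of model-averaged rates (mean and spread across
        reconstructions).
    raw
        Per axis, the underlying arrays (``aicc``: R × M, ``loglik``,
        ``root``, ``rates``: R × M × n_states, ``avg_rates``: R × n_states).
    """

    model_names: list[str]
    states: tuple[str, ...]
    n_reconstructions: int
    se_mode: str
    fits: dict[str, pd.DataFrame]
    support: dict[str, pd.DataFrame]
    averaged_rates: pd.DataFrame
    raw: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    @property
    def axes(self) -> list[str]:
        return list(self.fits)


def _spread(values: np.ndarray, se_mode: str, axis: int = 0) -> np.ndarray:
    sd = values.std(axis=axis, ddof=1) if values.shape[axis] > 1 else np.zeros_like(
        values.mean(axis=axis)
    )
    if se_mode == "sem":
        return sd / np.sqrt(values.shape[axis])
    if se_mode != "sd":
        raise ValueError("se_mode must be 'sd' or 'sem'")
    return sd


def _preferred_index(aicc_row: np.ndarray, ks: np.ndarray) -> int:
    """Index of the preferred model: min AICc, exact ties to the smaller k."""
    best = aicc_row.min()
    tied = np.flatnonzero(aicc_row == best)
    return int(tied[np.argmin(ks[tied])])


def run_ensemble(
    maps: Sequence[StochasticMap],
    trait_table: pd.DataFrame,
    models: Sequence[RateModelSpec] | None = None,
    states: Sequence[str] = HABITAT_STATES,
    se_mode: str = "sd",
    axes: Sequence[str] | None = None,
) -> EnsembleSummary:
    """Fit every model on every reconstruction for every trait axis.

    ``trait_table`` is a species-indexed table with score columns
    ``pc1..pcK`` and matching sampling-variance columns ``var1..varK``
    (missing variance columns mean error-free species values).
    """
    models = list(models) if models is not None else build_model_set(states)
    if not models:
        raise ValueError("empty model set")
    if not len(maps):
        raise ValueError("empty reconstruction ensemble")
    states = tuple(states)
    species = set(trait_table.index)
    tips = set(maps[0].tree.labels)
    if species != tips:
        raise ValueError(
            "species mismatch between trait table and maps: "
            f"only in traits {sorted(species - tips)}, only in maps {sorted(tips - species)}"
        )
    axis_cols = _axis_columns(trait_table)
    if axes is not None:
        axis_cols = [(a, v) for a, v in axis_cols if a in set(axes)]
    names = [m.name for m in models]
    ks = np.array([m.k for m in models])
    R, M, K = len(maps), len(models), len(states)

    fits_out: dict[str, pd.DataFrame] = {}
    support_out: dict[str, pd.DataFrame] = {}
    raw: dict[str, dict[str, np.ndarray]] = {}
    avg_blocks = {}

    stacks = [m.shared_path_stack(states) for m in maps]
    for axis, var_col in axis_cols:
        x = trait_table[axis]
        sv = trait_table[var_col] if var_col else None
        aicc_arr = np.empty((R, M))
        ll_arr = np.empty((R, M))
        root_arr = np.empty((R, M))
        rate_arr = np.empty((R, M, K))
        for r, smap in enumerate(maps):
            lik = BMLikelihood(smap, x, sv, states, stack=stacks[r])
            start = None
            one_rate = [m for m in models if m.n_classes == 1]
            if one_rate:
                base_fit = lik.fit(one_rate[0])
                start = float(base_fit.rates[0])
            # fit the richest model first; its optimum, collapsed onto each
            # restricted partition, seeds the nested fits
            order = sorted(range(M), key=lambda j: -models[j].n_classes)
            fits_row: dict[int, object] = {}
            full_fit = None
            for j in order:
                model = models[j]
                if one_rate and model is one_rate[0]:
                    fits_row[j] = base_fit
                    continue
                extra, fan = None, True
                if full_fit is not None and model.n_classes < full_fit.model.n_classes:
                    collapsed = [
                        np.mean([full_fit.rate_for(s) for s in states if model.class_of(s) == c])
                        for c in range(model.n_classes)
                    ]
                    extra, fan = [collapsed], False
                fits_row[j] = lik.fit(model, start_rate=start, extra_starts=extra, fan=fan)
                if full_fit is None:
                    full_fit = fits_row[j]
            for j, model in enumerate(models):
                fit = fits_row[j]
                aicc_arr[r, j] = fit.aicc_score
                ll_arr[r, j] = fit.loglik
                root_arr[r, j] = fit.root
                rate_arr[r, j] = [fit.rate_for(s) for s in states]
        # headline table from mean AICc
        mean_aicc = aicc_arr.mean(axis=0)
        delta = mean_aicc - mean_aicc.min()
        weights = akaike_weights(mean_aicc)
        tbl = pd.DataFrame({"model": names, "k": ks})
        tbl["root_mean"] = root_arr.mean(axis=0)
        tbl["root_se"] = _spread(root_arr, se_mode)
        for s_i, s in enumerate(states):
            tbl[f"rate_{s}_mean"] = rate_arr[:, :, s_i].mean(axis=0)
            tbl[f"rate_{s}_se"] = _spread(rate_arr[:, :, s_i], se_mode)
        tbl["neg_loglik_mean"] = (-ll_arr).mean(axis=0)
        tbl["neg_loglik_se"] = _spread(-ll_arr, se_mode)
        tbl["aicc_mean"] = mean_aicc
        tbl["aicc_se"] = _spread(aicc_arr, se_mode)
        tbl["delta_aicc"] = delta
        tbl["weight"] = weights
        fits_out[axis] = tbl
        # per-reconstruction support
        delta_rows = aicc_arr - aicc_arr.min(axis=1, keepdims=True)
        preferred = np.array([_preferred_index(aicc_arr[r], ks) for r in range(R)])
        pct_pref = np.array([(preferred == j).mean() * 100.0 for j in range(M)])
        pct_disf = (delta_rows > DISFAVOURED_DELTA).mean(axis=0) * 100.0
        lohi = np.percentile(delta_rows, [2.5, 97.5], axis=0)
        support_out[axis] = pd.DataFrame(
            {
                "model": names,
                "delta_lo": lohi[0],
                "delta_hi": lohi[1],
                "pct_preferred": pct_pref,
                "pct_disfavoured": pct_disf,
            }
        )
        # per-reconstruction model averaging
        w_rows = np.stack([akaike_weights(aicc_arr[r]) for r in range(R)])
        avg = np.einsum("rm,rmk->rk", w_rows, rate_arr)
        avg_blocks[axis] = avg
        raw[axis] = {
            "aicc": aicc_arr,
            "loglik": ll_arr,
            "root": root_arr,
            "rates": rate_arr,
            "avg_rates": avg,
        }

    rows = []
    for axis, avg in avg_blocks.items():
        for s_i, s in enumerate(states):
            rows.append(
                {
                    "axis": axis,
                    "habitat": s,
                    "rate_mean": avg[:, s_i].mean(),
                    "rate_se": float(_spread(avg[:, s_i : s_i + 1], se_mode)[0]),
                }
            )
    averaged = pd.DataFrame(rows)
    return EnsembleSummary(
        model_names=names,
        states=states,
        n_reconstructions=R,
        se_mode=se_mode,
        fits=fits_out,
        support=support_out,
        averaged_rates=averaged,
        raw=raw,
    )


# ---------------------------------------------------------------------------
# Clade-restricted rates
# ---------------------------------------------------------------------------


def clade_rate_summary(
    maps: Sequence[StochasticMap],
    trait_table: pd.DataFrame,
    clades: Mapping[str, Iterable[str]],
    states: Sequence[str] = HABITAT_STATES,
    size_axis: str = "pc1",
    shape_axes: Sequence[str] = ("pc2", "pc3", "pc4"),
    se_mode: str = "sd",
) -> pd.DataFrame:
    """Within-clade per-habitat rates of size and shape evolution.

    For each named clade the full multi-rate model is refitted on the
    censored species subset: the rows/columns of the shared-path matrices
    belonging to the clade's tips (habitat classes with zero occupancy
    inside the clade are dropped and reported as NaN).  The size rate is the
    mean fitted rate on ``size_axis`` across reconstructions; the shape rate
    is the sum of the mean rates on ``shape_axes``.  Reconstructions in
    which a clade is not monophyletic are skipped and counted.
    """
    states = tuple(states)
    axes = [size_axis, *shape_axes]
    rows = []
    for clade_name, tip_labels in clades.items():
        tip_labels = list(tip_labels)
        per_axis: dict[str, list[np.ndarray]] = {a: [] for a in axes}
        skipped = 0
        for smap in maps:
            tree = smap.tree
            try:
                mono = tree.is_monophyletic(tip_labels)
            except ValueError:
                mono = False
            if not mono:
                skipped += 1
                continue
            idx = np.array([tree.labels.index(t) for t in tip_labels])
            stack = smap.shared_path_stack(states)[:, idx[:, None], idx[None, :]]
            present = [s for k, s in enumerate(states) if stack[k].sum() > 0]
            sub_model = RateModelSpec.from_mapping(
                "clade full", {s: i for i, s in enumerate(present)}
            )
            keep = np.array([k for k, s in enumerate(states) if s in present])
            sub_stack = stack[keep]
            for axis in axes:
                var_col = "var" + axis[2:]
                sv = (
                    trait_table[var_col].reindex(tip_labels)
                    if var_col in trait_table.columns
                    else None
                )
                lik = BMLikelihood(
                    None,
                    trait_table[axis].reindex(tip_labels),
                    sv,
                    states=present,
                    stack=sub_stack,
                    labels=tip_labels,
                )
                fit = lik.fit(sub_model)
                full = np.full(len(states), np.nan)
                for i, s in enumerate(present):
                    full[states.index(s)] = fit.rates[i]
                per_axis[axis].append(full)
        if skipped:
            logger.warning(
                "clade %s not monophyletic in %d/%d reconstructions; skipped",
                clade_name,
                skipped,
                len(maps),
            )
        if not per_axis[size_axis]:
            continue
        size = np.stack(per_axis[size_axis])
        shape = [np.stack(per_axis[a]) for a in shape_axes if per_axis[a]]
        for s_i, s in enumerate(states):
            shape_mean = float(np.sum([b[:, s_i].mean() for b in shape]))
            shape_se = float(
                np.sqrt(np.sum([_spread(b[:, s_i : s_i + 1], se_mode)[0] ** 2 for b in shape]))
            )
            rows.append(
                {
                    "clade": clade_name,
                    "habitat": s,
                    "size_rate": size[:, s_i].mean(),
                    "size_se": float(_spread(size[:, s_i : s_i + 1], se_mode)[0]),
                    "shape_rate": shape_mean,
                    "shape_se": shape_se,
                    "n_used": size.shape[0],
                    "n_skipped": skipped,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _fmt_pm(mean: float, se: float, nd: int) -> str:
    return f"{mean:.{nd}f} ± {se:.{nd}f}"


def report(summary: EnsembleSummary) -> dict[str, pd.DataFrame]:
    """Human-readable tables (deterministic formatting).

    ``<axis>_fits`` mirrors the classic model-comparison layout (Model, Root
    state, one rate column per habitat, −lnL, AICc, ΔAICc, Weight; values as
    ``mean ± spread``, AICc/ΔAICc to 2 decimals, weights to 3).
    ``<axis>_support`` carries the mid-95% ΔAICc interval, % preferred and
    % disfavoured.  ``averaged_rates`` is numeric.
    """
    if not summary.fits:
        raise ValueError("summary contains no fitted axes")
    out: dict[str, pd.DataFrame] = {}
    for axis, tbl in summary.fits.items():
        rows = []
        for _, row in tbl.iterrows():
            rec = {
                "Model": row["model"],
                "Root state": _fmt_pm(row["root_mean"], row["root_se"], 3),
            }
            for s in summary.states:
                rec[f"Rate {s}"] = _fmt_pm(
                    row[f"rate_{s}_mean"], row[f"rate_{s}_se"], 3
                )
            rec["-lnL"] = _fmt_pm(row["neg_loglik_mean"], row["neg_loglik_se"], 2)
            rec["AICc"] = _fmt_pm(row["aicc_mean"], row["aicc_se"], 2)
            rec["dAICc"] = f"{row['delta_aicc']:.2f}"
            rec["Weight"] = f"{row['weight']:.3f}"
            rows.append(rec)
        out[f"{axis}_fits"] = pd.DataFrame(rows)
        sup = summary.support[axis]
        out[f"{axis}_support"] = pd.DataFrame(
            {
                "Model": sup["model"],
                "95% dAICc interval": [
                    f"({lo:.2f}, {hi:.2f})"
                    for lo, hi in zip(sup["delta_lo"], sup["delta_hi"])
                ],
                "% Preferred": [f"{v:.1f}" for v in sup["pct_preferred"]],
                "% Disfavoured": [f"{v:.1f}" for v in sup["pct_disfavoured"]],
            }
        )
    out["averaged_rates"] = summary.averaged_rates.copy()
    return out


def write_report(summary: EnsembleSummary, outdir: str) -> list[str]:
    """Write the report tables as TSV files; returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for name, tbl in report(summary).items():
        path = os.path.join(outdir, f"{name}.tsv")
        tbl.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
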