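"""Species means, correlation-matrix PCA, and per-species sampling variances.

Species trait values are arithmetic means of log-transformed linear
measurements over the individuals measured for that species.  A PCA on the
correlation matrix of those species means yields the trait axes used for
model fitting; individuals are then pushed through the same standardization
and loadings to estimate the pooled within-species variance on each axis,
and each species' sampling variance is that pooled variance divided by its
individual count.

The natural log is used for the log transform; the base has no effect on a
correlation-matrix PCA (it rescales columns uniformly) and only shifts
species means by a constant factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 13 linear measurements, in conventional reporting order.
MEASUREMENT_VARS: tuple[str, ...] = (
    "snout_vent_length",
    "tail_length",
    "body_width",
    "pectoral_width",
    "pelvic_width",
    "humerus_length",
    "ulna_length",
    "carpal_length",
    "iv_metacarpal_length",
    "femur_length",
    "tibia_length",
    "tarsal_length",
    "iv_metatarsal_length",
)


def load_measurements(
    source, log: bool = True, species_col: str = "species"
) -> pd.DataFrame:
    """Read an individuals-by-measurements CSV.

    Expected columns: ``species``, optionally ``individual_id``, plus the
    measurement columns (raw mm).  With ``log=True`` (default) the natural
    log is applied to every measurement column.
    """
    df = pd.read_csv(source)
    if species_col not in df.columns:
        raise ValueError(f"measurement CSV lacks a {species_col!r} column")
    value_cols = [c for c in df.columns if c not in (species_col, "individual_id")]
    vals = df[value_cols].astype(float)
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("non-finite measurement values")
    if log:
        if (vals.to_numpy() <= 0).any():
            raise ValueError("measurements must be positive to log-transform")
        vals = np.log(vals)
    out = pd.concat([df[[species_col]], vals], axis=1)
    return out


def species_means(
    measurements: pd.DataFrame, species_col: str = "species"
) -> pd.DataFrame:
    """Per-species arithmetic means of the (log-scale) measurement columns."""
    value_cols = [
        c
        for c in measurements.columns
        if c not in (species_col, "individual_id")
    ]
    return measurements.groupby(species_col, sort=True)[value_cols].mean()


@dataclass
class PCAResult:
    """Eigendecomposition of the correlation matrix of species means.

    Attributes
    ----------
    loadings
        Variables × components orthonormal eigenvector matrix; within each
        component the largest-magnitude loading is made positive.
    eigenvalues
        Component variances of the standardized data; they sum to the number
        of variables.
    scores
        Species scores: standardized species means projected on the loadings.
    pct_total
        Eigenvalue as a percentage of total variance.
    pct_shape
        For components beyond the first: eigenvalue as a percentage of the
        variance not captured by component 1.
    center, scale
        Column means and standard deviations of the species-mean table used
        for standardization (the PCA's own frame).
    """

    loadings: pd.DataFrame
    eigenvalues: pd.Series
    scores: pd.DataFrame
    pct_total: pd.Series
    pct_shape: pd.Series
    center: pd.Series
    scale: pd.Series

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    def project(self, data: pd.DataFrame) -> pd.DataFrame:
        """Standardize rows by the PCA frame and project on the loadings."""
        Z = (data[self.loadings.index] - self.center) / self.scale
        return pd.DataFrame(
            Z.to_numpy() @ self.loadings.to_numpy(),
            index=data.index,
            columns=self.components,
        )


def pca_correlation(means: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a species × variable mean table.

    Components are ordered by decreasing eigenvalue.  The percent of *shape*
    variation attributed to component ``j >= 2`` is its eigenvalue divided by
    the total variance remaining after component 1.
    """
    if len(means) < 2:
        raise ValueError("PCA requires at least two species")
    X = means.to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        names = [means.columns[i] for i in zero]
        raise ValueError(f"zero-variance variable(s): {names}")
    Z = (X - center) / scale
    R = (Z.T @ Z) / (len(means) - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order].clip(min=0.0)
    eigvec = eigvec[:, order]
    # sign convention: the largest-magnitude loading in each component is positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"pc{j + 1}" for j in range(eigvec.shape[1])]
    total = float(eigval.sum())
    shape_total = total - float(eigval[0])
    pct_shape = np.full(len(eigval), np.nan)
    if shape_total > 0:
        pct_shape[1:] = eigval[1:] / shape_total * 100.0
    loadings = pd.DataFrame(eigvec, index=means.columns, columns=comps)
    scores = pd.DataFrame(Z @ eigvec, index=means.index, columns=comps)
    return PCAResult(
        loadings=loadings,
        eigenvalues=pd.Series(eigval, index=comps, name="eigenvalue"),
        scores=scores,
        pct_total=pd.Series(eigval / total * 100.0, index=comps, name="pct_total"),
        pct_shape=pd.Series(pct_shape, index=comps, name="pct_shape"),
        center=pd.Series(center, index=means.columns),
        scale=pd.Series(scale, index=means.columns),
    )


def sampling_variances(
    measurements: pd.DataFrame,
    pca: PCAResult,
    n_components: int = 4,
    species_col: str = "species",
) -> pd.DataFrame:
    """Species scores with per-species sampling variances on each PC axis.

    Individuals are standardized by the species-mean frame of the fitted PCA
    and projected through its loadings.  The pooled within-species variance
    of component ``c`` is ``sum_s sum_i (score_si - mean_s)^2 / (N - S)``
    with ``N`` individuals in total and ``S`` species; the sampling variance
    of species ``s`` is the pooled variance divided by ``n_s``.  Species
    measured once contribute nothing to the pooled estimate but receive
    ``pooled / 1`` like any other species.

    Returns a trait table with columns ``pc1..pcK, var1..varK, n`` indexed by
    species.
    """
    comps = pca.components[:n_components]
    value_cols = list(pca.loadings.index)
    missing = set(value_cols) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements lack PCA variables: {sorted(missing)}")
    groups = measurements.groupby(species_col, sort=True)
    n_per = groups.size()
    N, S = int(n_per.sum()), len(n_per)
    if N <= S:
        raise ValueError(
            "pooled within-species variance is undefined when every species has a "
            "single individual; supply replicate measurements or set an explicit "
            "sampling-variance floor"
        )
    ind_scores = pca.project(measurements[value_cols])[comps]
    ind_scores[species_col] = measurements[species_col].to_numpy()
    centered = ind_scores.groupby(species_col, sort=True)[comps].transform(
        lambda x: x - x.mean()
    )
    pooled = (centered.to_numpy() ** 2).sum(axis=0) / (N - S)
    # species scores from the species-mean table (equal to per-species means of
    # individual scores, because projection is affine)
    scores = pca.scores.loc[n_per.index, comps]
    out = scores.copy()
    for j, c in enumerate(comps):
        out[f"var{j + 1}"] = pooled[j] / n_per.to_numpy()
    out["n"] = n_per.to_numpy()
    out.index.name = "species"
    return out


def pooled_within_variance(
    measurements: pd.DataFrame,
    pca: PCAResult,
    n_components: int = 4,
    species_col: str = "species",
) -> pd.Series:
    """The pooled within-species variance per component (helper for reports)."""
    tt = sampling_variances(measurements, pca, n_components, species_col)
    comps = pca.components[:n_components]
    var_cols = [f"var{j + 1}" for j in range(len(comps))]
    pooled = tt[var_cols].mul(tt["n"], axis=0).iloc[0]
    pooled.index = comps
    return pooled


def trait_table_to_csv(trait_table: pd.DataFrame, path: str) -> None:
    trait_table.to_csv(path)


def trait_table_from_csv(source) -> pd.DataFrame:
    df = pd.read_csv(source)
    if "species" not in df.columns:
        raise ValueError("trait table CSV lacks a 'species' column")
    return df.set_index("species")
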