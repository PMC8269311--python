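"""Unsupervised quality control: PCA, heatmap matrices, ground merging, outlier flagging.

PCA runs on centered, unscaled data (samples as observations, metabolites
as features).  Heatmap matrices are standard-scaled per metabolite and then
rescaled into [-1, 1] by the global maximum absolute standardized value;
row/column orders come from complete-linkage hierarchical clustering of
Euclidean distances.  Outlier flagging operationalizes the leakage-sample
diagnosis: a sample holding the per-metabolite maximum for almost all
metabolites is reported, and removal is an explicit, auditable decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

from .model import RMATable, ValidationError


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # metabolite x component
    explained_variance_fraction: np.ndarray

    def validate(self) -> None:
        evf = self.explained_variance_fraction
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12) or evf.sum() > 1 + 1e-9:
            raise ValidationError("explained variance fractions must lie in [0,1] and sum to <= 1")
        if np.any(np.diff(evf) > 1e-12):
            raise ValidationError("explained variance fractions must be non-increasing")


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame  # metabolite x sample, entries in [-1, 1]
    row_order: list
    col_order: list


def run_pca(table: RMATable, n_components: int | None = None) -> PcaResult:
    """PCA on centered, unscaled data with a deterministic sign convention.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    if table.values.isna().any().any():
        raise ValidationError("PCA input must not contain missing values")
    x = table.values.to_numpy(dtype=float).T  # samples x metabolites
    n_samples, n_feat = x.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_feat)
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero total variance is a legal degenerate input
        scores = pca.fit_transform(x)
    loadings = pca.components_.T  # metabolite x component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    total_var = np.var(x - x.mean(axis=0), ddof=0) * n_feat  # per-sample mean of squared deviations
    comps = [f"PC{j + 1}" for j in range(k)]
    evf = pca.explained_variance_ratio_.copy()
    if not np.isfinite(evf).all() or total_var == 0:
        evf = np.zeros(k)
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.values.columns, columns=comps),
        loadings=pd.DataFrame(loadings, index=table.values.index, columns=comps),
        explained_variance_fraction=evf,
    )


def heatmap_matrix(table: RMATable) -> HeatmapMatrix:
    """Standard-scale per metabolite, rescale to [-1, 1] globally, order by complete linkage."""
    if table.values.isna().any().any():
        raise ValidationError("heatmap input must not contain missing values")
    x = table.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero_var = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance metabolite rows set to 0 in heatmap")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[zero_var, :] = 0.0
    gmax = np.max(np.abs(z))
    if gmax > 0:
        z = z / gmax
    values = pd.DataFrame(z, index=table.values.index, columns=table.values.columns)
    row_order = _cluster_order(z)
    col_order = _cluster_order(z.T)
    return HeatmapMatrix(
        values=values,
        row_order=[table.values.index[i] for i in row_order],
        col_order=[table.values.columns[i] for i in col_order],
    )


def _cluster_order(x: np.ndarray) -> list:
    if x.shape[0] < 2:
        return list(range(x.shape[0]))
    lk = linkage(x, method="complete", metric="euclidean")
    return list(leaves_list(lk))


def merge_ground(table: RMATable, sample_ids, merged_id: str | None = None) -> RMATable:
    """Replace the listed ground samples by their arithmetic mean column."""
    sample_ids = list(sample_ids)
    for sid in sample_ids:
        if sid not in table.values.columns:
            raise ValidationError(f"unknown sample id {sid!r}")
        if table.samples.loc[sid, "group"] != "ground":
            raise ValidationError(f"sample {sid!r} is not a ground sample")
    if merged_id is None:
        merged_id = "+".join(sample_ids)
    mean_col = table.values[sample_ids].mean(axis=1)
    keep = [c for c in table.values.columns if c not in set(sample_ids)]
    values = table.values[keep].copy()
    values[merged_id] = mean_col
    samples = table.samples.loc[keep].copy()
    samples.loc[merged_id] = table.samples.loc[sample_ids[0]]
    return RMATable(
        values=values,
        samples=samples,
        platform=table.platform,
        blank_subtracted=table.blank_subtracted,
        scaled_by=table.scaled_by,
    )


def flag_outlier_samples(table: RMATable, threshold: float = 0.8) -> list:
    """Score each sample by the fraction of metabolites where it holds the maximum.

    Ties split their weight evenly.  Returns ``[(sample_id, score), ...]``
    sorted by descending score, restricted to scores >= threshold; removal
    stays an explicit caller decision.
    """
    if table.values.shape[1] < 3:
        raise ValidationError("outlier flagging needs at least 3 samples")
    x = table.values.to_numpy(dtype=float)
    scores = np.zeros(x.shape[1])
    for row in x:
        if np.all(np.isnan(row)):
            continue
        rowmax = np.nanmax(row)
        at_max = np.nan_to_num(row, nan=-np.inf) == rowmax
        scores[at_max] += 1.0 / at_max.sum()
    scores /= x.shape[0]
    flagged = [
        (table.values.columns[i], float(scores[i]))
        for i in np.argsort(-scores)
        if scores[i] >= threshold
    ]
    return flagged


def outlier_scores(table: RMATable) -> pd.Series:
    """All samples' max-holding fractions (diagnostic companion of :func:`flag_outlier_samples`)."""
    x = table.values.to_numpy(dtype=float)
    scores = np.zeros(x.shape[1])
    for row in x:
        if np.all(np.isnan(row)):
            continue
        rowmax = np.nanmax(row)
        at_max = np.nan_to_num(row, nan=-np.inf) == rowmax
        scores[at_max] += 1.0 / at_max.sum()
    scores /= x.shape[0]
    return pd.Series(scores, index=table.values.columns, name="max_fraction")
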