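"""Inter-metabolite Pearson correlation and conserved-cluster mining.

Correlations are computed over all biological samples of a dataset,
ignoring gravity conditions: metabolites coupled through shared
biochemistry move together across samples regardless of group.  A
candidate cluster is any subtree of the dataset-1 dendrogram (average
linkage, Euclidean distance on correlation-matrix rows — equivalently the
groups obtained by cutting the dendrogram at successive heights); it is
accepted as a conserved, potentially gravity-sensitive cluster when its
mean pairwise |r| reaches the threshold in *both* datasets.  |r| is used
because strong anticorrelation is as informative as strong correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .model import ClusterSet, RMATable, ValidationError


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # symmetric metabolite x metabolite
    order: list  # clustering permutation (metabolite ids)

    @property
    def metabolites(self):
        return list(self.r.index)


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    zero = (sd == 0) | ~np.isfinite(sd)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance metabolites: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def correlation_matrix(table: RMATable, cluster: bool = True) -> CorrelationMatrix:
    """Pairwise Pearson correlation over all samples, with an average-linkage row order."""
    if table.values.shape[1] < 3:
        raise ValidationError("correlation needs >= 3 samples")
    if table.values.isna().any().any():
        raise ValidationError("correlation input must not contain missing values")
    r = _pearson_matrix(table.values.to_numpy(dtype=float))
    frame = pd.DataFrame(r, index=table.values.index, columns=table.values.index)
    order = _linkage_order(frame) if cluster else list(frame.index)
    return CorrelationMatrix(r=frame, order=order)


def _linkage_order(r: pd.DataFrame) -> list:
    if len(r) < 2:
        return list(r.index)
    lk = linkage(r.to_numpy(), method="average", metric="euclidean")
    return [r.index[i] for i in leaves_list(lk)]


def shared_panel_matrix(cm: CorrelationMatrix, shared_ids, order_from: CorrelationMatrix | None = None) -> CorrelationMatrix:
    """Restrict to the shared metabolite panel.

    Without ``order_from`` the restricted matrix is re-clustered (the
    dataset-1 role); with it, the other matrix's order is applied verbatim
    so both heatmaps align row by row (the dataset-2 role).
    """
    shared_ids = list(shared_ids)
    missing = [m for m in shared_ids if m not in cm.r.index]
    if missing:
        raise ValidationError(f"ids absent from the correlation matrix: {missing}")
    sub = cm.r.loc[shared_ids, shared_ids]
    if order_from is not None:
        order = [m for m in order_from.order if m in set(shared_ids)]
        if len(order) != len(shared_ids):
            raise ValidationError("order_from does not cover the shared panel")
        sub = sub.loc[order, order]
        return CorrelationMatrix(r=sub, order=order)
    order = _linkage_order(sub)
    sub = sub.loc[order, order]
    return CorrelationMatrix(r=sub, order=order)


def _mean_abs_offdiag(r: pd.DataFrame, ids) -> float:
    sub = r.loc[list(ids), list(ids)].to_numpy()
    n = sub.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.mean(np.abs(sub[mask])))


def _dendrogram_groups(r: pd.DataFrame) -> list:
    """All groups obtained by cutting the dendrogram at successive heights (= all subtrees)."""
    ids = list(r.index)
    n = len(ids)
    if n < 2:
        return []
    lk = linkage(r.to_numpy(), method="average", metric="euclidean")
    members = {i: [ids[i]] for i in range(n)}
    groups = []
    for k, (a, b, _, _) in enumerate(lk):
        merged = members[int(a)] + members[int(b)]
        members[n + k] = merged
        groups.append(tuple(sorted(merged)))
    return groups


def find_conserved_clusters(cm1: CorrelationMatrix, cm2: CorrelationMatrix,
                            threshold: float = 0.8, min_size: int = 2) -> ClusterSet:
    """Maximal metabolite groups with mean pairwise |r| >= threshold in both datasets.

    Candidates are the dataset-1 dendrogram subtrees; accepted groups
    contained in a larger accepted group are dropped.  Deterministic for a
    given input order, and returned clusters never overlap.
    """
    if list(cm1.r.index) != list(cm2.r.index):
        raise ValidationError("correlation matrices must share the metabolite panel and order")
    accepted = []
    for ids in _dendrogram_groups(cm1.r):
        if len(ids) < min_size:
            continue
        r1 = _mean_abs_offdiag(cm1.r, ids)
        if r1 < threshold:
            continue
        r2 = _mean_abs_offdiag(cm2.r, ids)
        if r2 < threshold:
            continue
        accepted.append((ids, r1, r2))
    # keep maximal groups only (dendrogram subtrees are nested or disjoint)
    maximal = []
    for ids, r1, r2 in sorted(accepted, key=lambda t: -len(t[0])):
        if any(set(ids) <= set(big[0]) for big in maximal):
            continue
        maximal.append((ids, r1, r2))
    maximal.sort(key=lambda t: (-len(t[0]), t[0]))
    return ClusterSet(clusters=maximal, threshold=threshold, min_size=min_size)
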