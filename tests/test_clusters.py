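"""Correlation matrices and conserved-cluster mining."""

import numpy as np
import pandas as pd
import pytest

import exofoot as ef
from exofoot.clusters import CorrelationMatrix

from conftest import make_rma


def _rma_from_rows(rows, n_flight=2):
    n_samples = len(next(iter(rows.values())))
    cols = {f"S{j}": [rows[m][j] for m in rows] for j in range(n_samples)}
    groups = {f"S{j}": ("flight" if j < n_flight else "ground") for j in range(n_samples)}
    return make_rma(cols, groups, metabolite_ids=list(rows))


def test_correlation_of_duplicate_and_negated_rows():
    table = _rma_from_rows({
        "A": [1.0, 2.0, 5.0, 3.0],
        "A2": [1.0, 2.0, 5.0, 3.0],
        "NEG": [-1.0, -2.0, -5.0, -3.0],
    })
    cm = ef.correlation_matrix(table, cluster=False)
    assert cm.r.loc["A", "A2"] == pytest.approx(1.0)
    assert cm.r.loc["A", "NEG"] == pytest.approx(-1.0)
    assert np.allclose(cm.r.to_numpy(), cm.r.to_numpy().T)
    assert np.allclose(np.diag(cm.r.to_numpy()), 1.0)


def test_correlation_matches_sum_formula_oracle():
    rng = np.random.default_rng(17)
    rows = {f"M{i}": rng.normal(size=6).tolist() for i in range(5)}
    cm = ef.correlation_matrix(_rma_from_rows(rows, n_flight=3), cluster=False)
    for a in rows:
        for b in rows:
            x, y = np.array(rows[a]), np.array(rows[b])
            n = len(x)
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(n * (y**2).sum() - y.sum() ** 2)
            assert cm.r.loc[a, b] == pytest.approx(num / den, abs=1e-12)


def test_zero_variance_metabolite_gets_zero_correlations():
    table = _rma_from_rows({"FLAT": [2.0, 2.0, 2.0, 2.0], "A": [1.0, 2.0, 3.0, 4.0]})
    with pytest.warns(UserWarning):
        cm = ef.correlation_matrix(table, cluster=False)
    assert cm.r.loc["FLAT", "A"] == 0.0
    assert cm.r.loc["FLAT", "FLAT"] == 1.0


def test_correlation_invariant_under_positive_affine_transform():
    rng = np.random.default_rng(23)
    rows = {f"M{i}": rng.normal(size=8).tolist() for i in range(4)}
    cm1 = ef.correlation_matrix(_rma_from_rows(rows, n_flight=4), cluster=False)
    rows["M0"] = (np.array(rows["M0"]) * 3.5 + 11.0).tolist()
    cm2 = ef.correlation_matrix(_rma_from_rows(rows, n_flight=4), cluster=False)
    assert np.allclose(cm1.r.to_numpy(), cm2.r.to_numpy(), atol=1e-12)


def test_shared_panel_matrix_restriction_and_order_transfer(processed_pair):
    rma_tex, rma_cb, *_ = processed_pair
    shared = ef.shared_metabolites(rma_tex.values.index, rma_cb.values.index)
    cm_tex = ef.correlation_matrix(rma_tex, cluster=False)
    cm_cb = ef.correlation_matrix(rma_cb, cluster=False)
    cm1 = ef.shared_panel_matrix(cm_tex, shared)
    cm2 = ef.shared_panel_matrix(cm_cb, shared, order_from=cm1)
    assert cm1.r.shape == cm2.r.shape == (len(shared), len(shared))
    assert list(cm1.r.index) == list(cm2.r.index) == cm1.order
    # identity restriction keeps every metabolite
    full = ef.shared_panel_matrix(cm_tex, list(cm_tex.r.index))
    assert set(full.r.index) == set(cm_tex.r.index)
    with pytest.raises(ef.ValidationError):
        ef.shared_panel_matrix(cm_tex, ["NOT-A-METABOLITE"])


def _cm_from_matrix(ids, r):
    frame = pd.DataFrame(r, index=ids, columns=ids)
    return CorrelationMatrix(r=frame, order=list(ids))


def _block_matrix(ids, block, rho, background=0.0):
    n = len(ids)
    r = np.full((n, n), background)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if a in block and b in block:
                r[i, j] = rho
    np.fill_diagonal(r, 1.0)
    return r


def test_conserved_cluster_requires_both_datasets():
    ids = [f"M{i}" for i in range(10)]
    block = {"M0", "M1", "M2", "M3", "M4"}
    cm1 = _cm_from_matrix(ids, _block_matrix(ids, block, 0.95))
    cm2_block = _cm_from_matrix(ids, _block_matrix(ids, block, 0.9))
    cm2_flat = _cm_from_matrix(ids, _block_matrix(ids, block, 0.0))
    found = ef.find_conserved_clusters(cm1, cm2_block, threshold=0.8)
    assert [set(ids_) for ids_, _, _ in found.clusters] == [block]
    assert found.clusters[0][1] == pytest.approx(0.95)
    assert found.clusters[0][2] == pytest.approx(0.9)
    # correlated in dataset 1 only -> rejected
    assert ef.find_conserved_clusters(cm1, cm2_flat, threshold=0.8).clusters == []
    # unattainable threshold -> empty
    assert ef.find_conserved_clusters(cm1, cm2_block, threshold=1.01).clusters == []


def test_conserved_clusters_never_overlap_and_are_deterministic(default_pair):
    t_tex, t_cb, _ = default_pair
    rma_tex, _ = ef.preprocess_platform(t_tex)
    rma_cb, _ = ef.preprocess_platform(t_cb)
    shared = ef.shared_metabolites(rma_tex.values.index, rma_cb.values.index)
    cm1 = ef.shared_panel_matrix(ef.correlation_matrix(rma_tex, cluster=False), shared)
    cm2 = ef.shared_panel_matrix(ef.correlation_matrix(rma_cb, cluster=False), shared, order_from=cm1)
    cs_a = ef.find_conserved_clusters(cm1, cm2, 0.6, 2)
    cs_b = ef.find_conserved_clusters(cm1, cm2, 0.6, 2)
    assert cs_a.clusters == cs_b.clusters
    seen = set()
    for ids, r1, r2 in cs_a.clusters:
        assert len(ids) >= 2 and r1 >= 0.6 and r2 >= 0.6
        assert not (set(ids) & seen)
        seen |= set(ids)


def test_planted_block_recovered_on_favorable_seed():
    truth = ef.build_truth(ef.GeneratorConfig(seed=5, with_effects=False, with_outlier=False))
    d1 = ef.simple_design("TEXUS54", 5, 3, flight_condition="control", n_tech_reps=3, prefix="A")
    d2 = ef.simple_design("CELLBOX", 5, 3, flight_condition="control", n_tech_reps=3, prefix="B")
    r1, _ = ef.preprocess_platform(ef.generate_platform(d1, truth))
    r2, _ = ef.preprocess_platform(ef.generate_platform(d2, truth))
    shared = ef.shared_metabolites(r1.values.index, r2.values.index)
    cm1 = ef.shared_panel_matrix(ef.correlation_matrix(r1, cluster=False), shared)
    cm2 = ef.shared_panel_matrix(ef.correlation_matrix(r2, cluster=False), shared, order_from=cm1)
    cs = ef.find_conserved_clusters(cm1, cm2, 0.8, 2)
    yellow = set(ef.simulate.YELLOW_BLOCK)
    assert any(set(ids) == yellow for ids, _, _ in cs.clusters)
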