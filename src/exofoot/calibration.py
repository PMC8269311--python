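"""Calibration experiments: statistical validation of the pipeline on planted truth.

These routines re-run the pipeline on synthetic data with known ground
truth and measure recovery: type-I error of the Welch test under a null,
exact and noisy fold-change recovery, conserved-cluster recovery power and
false-positive count, and leakage-outlier flagging power.  They are used by
the acceptance harness and are part of the public surface so users can
re-validate after changing thresholds.

All experiments derive their per-repetition seeds from a single base seed.
"""

from __future__ import annotations

import numpy as np

from . import differential, preprocess, qc
from .clusters import correlation_matrix, find_conserved_clusters, shared_panel_matrix
from .crossplatform import shared_metabolites
from .simulate import (
    GeneratorConfig,
    YELLOW_BLOCK,
    PINK_BLOCK,
    build_truth,
    cellbox_design,
    generate_pair,
    generate_platform,
    simple_design,
    texus54_design,
)

_CONTRAST_CONDITION = {"hypg_vs_ground": "hypg", "ug_vs_ground": "ug", "flight_vs_ground": "longterm"}


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed)).generate_state(n) % (2**31)


def welch_null_rejection_rate(seed: int, n_reps: int = 10000, alpha: float = 0.05,
                              noise_cv: float = 0.1, n_flight: int = 5, n_ground: int = 3) -> float:
    """Fraction of null rejections of the two-sample test at level alpha.

    Both groups draw from the same log-normal (no planted effect), at the
    long-duration design's group sizes.
    """
    rng = np.random.default_rng(int(seed))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rejections = 0
    for _ in range(n_reps):
        f = np.exp(sigma * rng.standard_normal(n_flight))
        g = np.exp(sigma * rng.standard_normal(n_ground))
        if differential.test_two_sample(f, g) < alpha:
            rejections += 1
    return rejections / n_reps


def _planted_fc_errors(truth, rma, contrast, design):
    condition = _CONTRAST_CONDITION[contrast]
    records = differential.differential_records(rma, contrast, design)
    errors = []
    for r in records:
        effects = truth.metabolite_effects.get(r.metabolite_id, {})
        if condition in effects:
            true_fc = effects[condition]
            errors.append(abs(r.fc - true_fc) / abs(true_fc))
    return errors


def zero_noise_fc_recovery(seed: int) -> float:
    """Worst relative fold-change error of the end-to-end pipeline at zero noise.

    Cluster latents, censoring and the leakage outlier are disabled: the
    remaining structure is purely deterministic, so every planted effect
    (including the sign-inverting ones) must come back exactly.
    """
    t_tex, t_cb, truth = generate_pair(
        GeneratorConfig(seed=int(seed), noise_cv=0.0, missing_below_lod_prob=0.0,
                        with_blocks=False, with_outlier=False)
    )
    rma_tex, _ = preprocess.preprocess_platform(t_tex)
    rma_cb, _ = preprocess.preprocess_platform(t_cb, reference=rma_tex)
    errors = []
    errors += _planted_fc_errors(truth, rma_tex, "hypg_vs_ground", "single_sample")
    errors += _planted_fc_errors(truth, rma_tex, "ug_vs_ground", "single_sample")
    errors += _planted_fc_errors(truth, rma_cb, "flight_vs_ground", "two_sample")
    return float(max(errors))


def noisy_fc_recovery(seed: int, n_seeds: int = 200, noise_cv: float = 0.1) -> float:
    """Median relative fold-change error at the long-duration design under noise."""
    errors = []
    for s in _spawn_seeds(seed, n_seeds):
        truth = build_truth(
            GeneratorConfig(seed=int(s), noise_cv=noise_cv, with_blocks=False, with_outlier=False)
        )
        table = generate_platform(cellbox_design(), truth)
        rma, _ = preprocess.preprocess_platform(table)
        errors += _planted_fc_errors(truth, rma, "flight_vs_ground", "two_sample")
    return float(np.median(errors))


def cluster_recovery(seed: int, n_seeds: int = 100, threshold: float = 0.8, min_size: int = 2,
                     n_flight: int = 5, n_ground: int = 3):
    """Recovery of the planted correlated block from two independent datasets.

    Two 8-sample single-condition layouts (no planted condition effects, so
    the background correlation is ~0) carry the same planted blocks; power
    is the fraction of repetitions whose conserved-cluster set contains the
    rho-0.95 block exactly, and any returned group that is not a subset of
    a planted block counts as false.
    """
    hits, false = 0, 0
    yellow, pink = set(YELLOW_BLOCK), set(PINK_BLOCK)
    for s in _spawn_seeds(seed, n_seeds):
        truth = build_truth(GeneratorConfig(seed=int(s), with_effects=False, with_outlier=False))
        d1 = simple_design("TEXUS54", n_flight, n_ground, flight_condition="control",
                           n_tech_reps=3, prefix="A")
        d2 = simple_design("CELLBOX", n_flight, n_ground, flight_condition="control",
                           n_tech_reps=3, prefix="B")
        r1, _ = preprocess.preprocess_platform(generate_platform(d1, truth))
        r2, _ = preprocess.preprocess_platform(generate_platform(d2, truth))
        shared = shared_metabolites(r1.values.index, r2.values.index)
        cm1 = shared_panel_matrix(correlation_matrix(r1, cluster=False), shared)
        cm2 = shared_panel_matrix(correlation_matrix(r2, cluster=False), shared, order_from=cm1)
        cs = find_conserved_clusters(cm1, cm2, threshold, min_size)
        if any(set(ids) == yellow for ids, _, _ in cs.clusters):
            hits += 1
        for ids, _, _ in cs.clusters:
            members = set(ids)
            if not (members <= yellow or members <= pink):
                false += 1
    return hits / n_seeds, false


def outlier_recovery(seed: int, n_seeds: int = 200, inflation: float = 3.0,
                     threshold: float = 0.8) -> float:
    """Power to flag the planted leakage sample on the long-duration platform."""
    hits = 0
    for s in _spawn_seeds(seed, n_seeds):
        _, t_cb, truth = generate_pair(GeneratorConfig(seed=int(s), outlier_inflation=inflation))
        rma, _ = preprocess.preprocess_platform(t_cb)
        flagged = qc.flag_outlier_samples(rma, threshold=threshold)
        target = truth.outlier_samples[0][0]
        if any(sid == target for sid, _ in flagged):
            hits += 1
    return hits / n_seeds


def pca_eigendecomposition_deviation(seed: int, n_tables: int = 5, n: int = 10) -> float:
    """Largest deviation of PCA variance fractions from a direct eigendecomposition."""
    import pandas as pd

    from .model import RMATable

    worst = 0.0
    for s in _spawn_seeds(seed, n_tables):
        rng = np.random.default_rng(int(s))
        x = rng.normal(loc=100.0, scale=40.0, size=(n, n))
        values = pd.DataFrame(x, index=[f"M{i}" for i in range(n)], columns=[f"S{j}" for j in range(n)])
        samples = pd.DataFrame(
            {"platform": "CELLBOX", "group": ["flight"] * (n // 2) + ["ground"] * (n - n // 2),
             "condition": "control"},
            index=values.columns,
        )
        table = RMATable(values=values, samples=samples, platform="CELLBOX", blank_subtracted=True)
        res = qc.run_pca(table)
        xc = x.T - x.T.mean(axis=0)
        w = np.clip(np.linalg.eigvalsh(xc.T @ xc / (n - 1))[::-1], 0, None)
        oracle = w / w.sum()
        k = len(res.explained_variance_fraction)
        worst = max(worst, float(np.max(np.abs(res.explained_variance_fraction - oracle[:k]))))
    return worst
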