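"""Differential analysis: fold change semantics, t-tests vs hand formulas, BH oracle, bands."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import exofoot as ef

from conftest import make_rma


# --- fold change ----------------------------------------------------------

@pytest.mark.parametrize("f, g, expected", [(10.0, 5.0, 2.0), (60.0, -1.0, -60.0), (7.0, 7.0, 1.0)])
def test_fold_change_ratio_and_inversion_sign(f, g, expected):
    fc = ef.fold_change(f, g)
    assert fc == pytest.approx(expected)
    assert (fc < 0) == (np.sign(f) != np.sign(g))


def test_fold_change_rejects_zero_ground():
    with pytest.raises(ZeroDivisionError):
        ef.fold_change(1.0, 0.0)


# --- t-tests --------------------------------------------------------------

def test_two_sample_null_and_separation_limits():
    assert ef.test_two_sample([5.0, 5.0, 5.0], [5.0, 5.0]) == 1.0
    p = ef.test_two_sample([100.0, 100.01, 99.99, 100.0], [0.0, 0.01, -0.01])
    assert p < 1e-8


def test_two_sample_matches_hand_welch_computation():
    rng = np.random.default_rng(3)
    f, g = rng.normal(10, 2, size=5), rng.normal(8, 3, size=3)
    p = ef.test_two_sample(f, g)
    # independent Welch computation: t statistic and Welch-Satterthwaite df
    vf, vg = f.var(ddof=1) / len(f), g.var(ddof=1) / len(g)
    t = (f.mean() - g.mean()) / math.sqrt(vf + vg)
    df = (vf + vg) ** 2 / (vf**2 / (len(f) - 1) + vg**2 / (len(g) - 1))
    p_hand = 2 * stats.t.sf(abs(t), df)
    assert p == pytest.approx(p_hand, rel=1e-12)


def test_single_sample_null_symmetric_and_hand_cases():
    assert ef.test_single_sample([4.0, 4.0, 4.0], 4.0) == 1.0
    assert ef.test_single_sample([10.0, 11.0, 12.0], 11.0) == pytest.approx(1.0)
    p = ef.test_single_sample([10.0, 12.0, 14.0], 0.0)
    t = 12.0 / (2.0 / math.sqrt(3))
    assert p == pytest.approx(2 * stats.t.sf(t, df=2), rel=1e-12)


def test_tests_reject_underpowered_inputs():
    with pytest.raises(ef.ValidationError):
        ef.test_two_sample([1.0], [2.0, 3.0])
    with pytest.raises(ef.ValidationError):
        ef.test_single_sample([1.0], 0.0)


# --- Benjamini-Hochberg ---------------------------------------------------

def _bh_oracle(p):
    """Brute-force BH: q(i) = min over j >= i of m*p(j)/j on sorted p."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = np.asarray(p)[order]
    for rank_i in range(m):
        q[rank_i] = min(min(m * sorted_p[j] / (j + 1) for j in range(rank_i, m)), 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def test_fdr_hand_example_and_boundaries():
    assert np.allclose(ef.estimate_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    assert np.allclose(ef.estimate_fdr([0.37]), [0.37])
    assert np.allclose(ef.estimate_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_fdr_matches_oracle_on_all_permutations_of_six_pvalues():
    rng = np.random.default_rng(8)
    base = rng.uniform(size=6)
    for perm in itertools.permutations(base):
        assert np.allclose(ef.estimate_fdr(list(perm)), _bh_oracle(list(perm)), atol=1e-12)


def test_fdr_preserves_order():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=30)
    q = ef.estimate_fdr(p)
    assert np.all((p[:, None] <= p[None, :]) <= (q[:, None] <= q[None, :] + 1e-15))


# --- banding and effect regions -------------------------------------------

@pytest.mark.parametrize(
    "fdr, band",
    [(0.10, "pp"), (0.349999, "pp"), (0.35, "p"), (0.42, "p"), (0.50, "p"), (0.500001, "ns"), (0.70, "ns")],
)
def test_band_assignment_boundaries(fdr, band):
    assert ef.assign_band(fdr) == band


@pytest.mark.parametrize(
    "fc, band, region",
    [
        (3.7, "pp", "strong_increase"),
        (-60.0, "p", "strong_inversion"),
        (0.3, "ns", "unclassified"),   # non-significant gate
        (0.3, "p", "weak_or_inverted_decrease"),
        (-0.3, "pp", "weak_or_inverted_decrease"),
        (2.0, "pp", "unclassified"),   # open boundaries
        (0.5, "pp", "unclassified"),
        (-0.5, "pp", "unclassified"),
        (-1.0, "pp", "unclassified"),
        (1.2, "pp", "unclassified"),
    ],
)
def test_effect_region_classification(fc, band, region):
    assert ef.classify_effect(fc, band) == region


@pytest.mark.parametrize("f, g, d", [(50.0, 20.0, 1), (-40.0, -10.0, -1), (3.0, 3.0, 0)])
def test_direction_of_change_sign(f, g, d):
    assert ef.direction_of_change(f, g) == d


# --- record-level integration ---------------------------------------------

def test_differential_records_on_planted_effects(zero_noise_pair):
    t_tex, t_cb, truth = zero_noise_pair
    rma_tex, _ = ef.preprocess_platform(t_tex)
    recs = {r.metabolite_id: r for r in ef.differential_records(rma_tex, "ug_vs_ground", "single_sample")}
    assert recs["Ornithine"].fc == pytest.approx(-41.0, rel=1e-9)
    assert recs["Ornithine"].direction == 1  # consumption at 1 g flips to production
    assert recs["Glucose"].fc == pytest.approx(0.4, rel=1e-9)
    assert recs["Glucose"].direction == 1  # less consumption = higher net value
    rma_cb, _ = ef.preprocess_platform(t_cb)
    recs_cb = {r.metabolite_id: r for r in ef.differential_records(rma_cb, "flight_vs_ground", "two_sample")}
    assert recs_cb["Rhamnose"].fc == pytest.approx(0.05, rel=1e-9)


def test_two_band_structure_on_noisy_pair(processed_pair):
    rma_tex, rma_cb, *_ = processed_pair
    recs = ef.differential_records(rma_cb, "flight_vs_ground", "two_sample")
    for r in recs:
        assert r.band == ef.assign_band(r.fdr)
        if r.band != "ns":
            assert r.fdr <= 0.5
        assert (r.fc < 0) == (np.sign(r.flight_mean) != np.sign(r.ground_mean) and r.flight_mean != 0)


def test_bar_export_filters_and_sd():
    table = make_rma(
        {"F1": [1.0, 5.0], "F2": [2.0, 6.0], "G1": [10.0, 1.0], "G2": [20.0, 2.0]},
        groups={"F1": "flight", "F2": "flight", "G1": "ground", "G2": "ground"},
    )
    records = [
        ef.DifferentialRecord("M1", "flight_vs_ground", 1.5, 15.0, 7.07, 0.1, 0.01, 0.1, "pp",
                              "weak_or_inverted_decrease", -1),
        ef.DifferentialRecord("M2", "flight_vs_ground", 5.5, 1.5, 0.707, 3.7, 0.9, 0.6, "ns",
                              "unclassified", 1),
    ]
    bars = ef.bar_export(table, records, fdr_cutoff=0.5)
    assert set(bars["metabolite_id"]) == {"M1"}  # fdr 0.6 excluded
    ground_row = bars[(bars["group"] == "ground")].iloc[0]
    assert ground_row["sd"] == pytest.approx(np.std([10.0, 20.0], ddof=1))
    assert ground_row["band_mark"] == "++"
    empty = ef.bar_export(table, [], fdr_cutoff=0.5)
    assert empty.empty and list(empty.columns) == ["metabolite_id", "contrast", "group", "mean", "sd", "band_mark"]
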