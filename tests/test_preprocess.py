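"""Preprocessing ladder: imputation rules, filters, blank handling, scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import exofoot as ef
from exofoot.model import Constants
from exofoot.preprocess import impute_technical_pair

from conftest import make_raw

NA = np.nan
C = Constants()


# --- technical-pair imputation -------------------------------------------

@pytest.mark.parametrize(
    "v1, v2, dataset_min, expected",
    [
        (45.0, NA, 30.0, (45.0, 6.0)),       # partner below LOD: 1/5 of dataset minimum
        (120.0, NA, 30.0, (120.0, 120.0)),   # partner above LOD: carry over
        (NA, 45.0, 30.0, (6.0, 45.0)),
        (80.0, 90.0, 30.0, (80.0, 90.0)),    # nothing missing
        (50.0, NA, 30.0, (50.0, 50.0)),      # LOD boundary: 50 is not below 50
    ],
)
def test_technical_pair_rule(v1, v2, dataset_min, expected):
    assert impute_technical_pair(v1, v2, dataset_min) == expected


def test_technical_pair_rejects_double_missing():
    with pytest.raises(ef.ValidationError):
        impute_technical_pair(NA, NA, 30.0)


# --- replicate collapsing and compartment combination ---------------------

def _one_sample_raw(reps, volumes=None):
    volumes = volumes or [1.0] * len(reps[0])
    cols = {}
    meta = {}
    for j, comp_vals in enumerate(zip(*reps)):
        pass
    # reps: list over replicates of per-compartment values -> build columns
    for comp_idx, vol in enumerate(volumes):
        for rep_idx in range(len(reps)):
            cid = f"S1_c{comp_idx + 1}_r{rep_idx + 1}"
            cols[cid] = [reps[rep_idx][comp_idx]]
            meta[cid] = ("sample", "flight", "longterm", "S1", f"c{comp_idx + 1}", vol, rep_idx + 1)
    return make_raw(cols, meta)


@pytest.mark.parametrize(
    "reps, expected",
    [([[10.0], [20.0]], 15.0), ([[10.0], [10.0], [10.0]], 10.0), ([[42.0]], 42.0)],
)
def test_collapse_technical_means_replicates(reps, expected):
    out = ef.collapse_technical(_one_sample_raw(reps))
    assert out.values.shape[1] == 1
    assert out.values.iloc[0, 0] == pytest.approx(expected)


@pytest.mark.parametrize(
    "comp_vals, volumes, expected",
    [([10.0, 20.0], [1.0, 1.0], 15.0), ([10.0, 20.0], [3.0, 1.0], 12.5), ([42.0], [2.0], 42.0)],
)
def test_combine_compartments_volume_weighted(comp_vals, volumes, expected):
    raw = _one_sample_raw([comp_vals], volumes=volumes)
    out = ef.combine_compartments(ef.collapse_technical(raw))
    assert out.values.shape[1] == 1
    assert out.values.iloc[0, 0] == pytest.approx(expected)


def test_zero_recovered_volumes_are_rejected():
    # the table invariant (volume > 0) already blocks the degenerate case
    with pytest.raises(ef.ValidationError):
        _one_sample_raw([[10.0, 20.0]], volumes=[0.0, 0.0])


# --- missingness filter ---------------------------------------------------

def _group_table(flight, ground):
    cols, meta = {}, {}
    for i, v in enumerate(flight, 1):
        cols[f"F{i}"] = [v]
        meta[f"F{i}"] = ("sample", "flight", "longterm", f"F{i}", "c1", 1.0, 0)
    for i, v in enumerate(ground, 1):
        cols[f"G{i}"] = [v]
        meta[f"G{i}"] = ("sample", "ground", "control", f"G{i}", "c1", 1.0, 0)
    return make_raw(cols, meta)


@pytest.mark.parametrize(
    "flight, ground, kept",
    [
        ([NA, NA, 80.0, 90.0, 70.0], [60.0, 70.0, 80.0], False),  # rule A: 2 missing, observed all > 50
        ([NA, NA, 40.0, 90.0, 70.0], [60.0, 70.0, 80.0], True),   # a low observed value blocks rule A
        ([NA, NA, NA, 90.0, 70.0], [NA, NA, 80.0], False),        # rule B: > half missing in both groups
        ([60.0, 70.0, 80.0, 90.0, 70.0], [60.0, 70.0, 80.0], True),
    ],
)
def test_missingness_filter_spec_cases(flight, ground, kept):
    out = ef.filter_missingness(_group_table(flight, ground))
    assert (out.values.shape[0] == 1) == kept


def _oracle_filter(flight, ground, lod=50.0):
    """Independent transliteration of the two narrative removal rules."""

    def rule_a(vals, thr):
        miss = sum(np.isnan(v) for v in vals)
        if miss < thr:
            return False
        observed = [v for v in vals if not np.isnan(v)]
        return all(v > lod for v in observed)

    if rule_a(flight, 2) or rule_a(ground, 1):
        return True
    fmiss = sum(np.isnan(v) for v in flight)
    gmiss = sum(np.isnan(v) for v in ground)
    return fmiss > len(flight) / 2 and gmiss > len(ground) / 2


def test_missingness_filter_matches_exhaustive_oracle():
    """All 3^8 missingness/value patterns for 5 flight + 3 ground samples."""
    states = [NA, 40.0, 80.0]
    patterns = list(itertools.product(states, repeat=8))
    cols = {f"F{i}": [] for i in range(1, 6)}
    cols.update({f"G{i}": [] for i in range(1, 4)})
    expected_removed = []
    for pat in patterns:
        flight, ground = list(pat[:5]), list(pat[5:])
        for i, v in enumerate(flight, 1):
            cols[f"F{i}"].append(v)
        for i, v in enumerate(ground, 1):
            cols[f"G{i}"].append(v)
        expected_removed.append(_oracle_filter(flight, ground))
    meta = {f"F{i}": ("sample", "flight", "longterm", f"F{i}", "c1", 1.0, 0) for i in range(1, 6)}
    meta.update({f"G{i}": ("sample", "ground", "control", f"G{i}", "c1", 1.0, 0) for i in range(1, 4)})
    table = make_raw(cols, meta)
    report = ef.PreprocessReport()
    out = ef.filter_missingness(table, report=report)
    removed = {m for m, _ in report.filtered_missingness}
    for mid, exp in zip(table.values.index, expected_removed):
        assert (mid in removed) == exp
    assert out.values.shape[0] == sum(not e for e in expected_removed)


# --- residual imputation, blanks, subtraction -----------------------------

def test_residual_mean_imputation_is_group_wise():
    table = _group_table([10.0, NA, 20.0, 30.0, 40.0], [100.0, NA, 300.0])
    out = ef.impute_residual_mean(table)
    assert out.values.loc["M1", "F2"] == pytest.approx(25.0)
    assert out.values.loc["M1", "G2"] == pytest.approx(200.0)


def test_residual_mean_imputation_fills_multiple_gaps_with_observed_mean():
    table = _group_table([10.0, NA, NA, 30.0, 20.0], [1.0, 2.0, 3.0])
    out = ef.impute_residual_mean(table)
    assert out.values.loc["M1", "F2"] == pytest.approx(20.0)
    assert out.values.loc["M1", "F3"] == pytest.approx(20.0)


def test_residual_mean_imputation_rejects_fully_missing_group():
    table = _group_table([NA, NA, NA, NA, NA], [1.0, 2.0, 3.0])
    with pytest.raises(ef.ValidationError):
        ef.impute_residual_mean(table)


def _blank_table(blank_vals, sample_val=500.0):
    cols = {"S1": [sample_val]}
    meta = {"S1": ("sample", "flight", "longterm", "S1", "c1", 1.0, 0)}
    for i, v in enumerate(blank_vals, 1):
        cols[f"B{i}"] = [v]
        meta[f"B{i}"] = ("blank", "none", "none", "BLANK", "c1", 1.0, i)
    return make_raw(cols, meta)


@pytest.mark.parametrize(
    "blanks, dataset_min, expected",
    [
        ([100.0, 110.0, 120.0], None, 110.0),
        ([100.0, NA, 120.0], None, 110.0),
        ([NA, NA, NA], 30.0, 6.0),  # all-missing blank falls back to min/5
    ],
)
def test_prepare_blank_rule(blanks, dataset_min, expected):
    table = _blank_table(blanks)
    blank = ef.prepare_blank(table, dataset_min=dataset_min)
    assert blank.iloc[0] == pytest.approx(expected)


@pytest.mark.parametrize("sample, blank, expected", [(150.0, 100.0, 50.0), (60.0, 100.0, -40.0), (100.0, 100.0, 0.0)])
def test_subtract_blank_signs_net_flux(sample, blank, expected):
    table = _blank_table([blank], sample_val=sample)
    rma = ef.subtract_blank(table, ef.prepare_blank(table))
    assert rma.blank_subtracted
    assert rma.values.loc["M1", "S1"] == pytest.approx(expected)


def test_subtract_blank_rejects_panel_mismatch():
    table = _blank_table([100.0])
    blank = pd.Series([1.0, 2.0], index=["M1", "M2"])
    with pytest.raises(ef.ValidationError):
        ef.subtract_blank(table, blank)


# --- problematic removal and scaling --------------------------------------

def _named_rma(platform):
    from conftest import make_rma

    return make_rma(
        {"S1": [1.0, 2.0, 3.0], "S2": [4.0, 5.0, 6.0], "S3": [7.0, 8.0, 9.0]},
        groups={"S1": "flight", "S2": "flight", "S3": "ground"},
        platform=platform,
        metabolite_ids=["Sucrose", "Nonadecane", "L-Valine"],
    )


def test_remove_problematic_respects_platform_restriction():
    cb = ef.remove_problematic(_named_rma("CELLBOX"))
    assert list(cb.values.index) == ["L-Valine"]
    tex = ef.remove_problematic(_named_rma("TEXUS54"))
    assert list(tex.values.index) == ["Sucrose", "L-Valine"]  # Sucrose fixative only on CELLBOX
    assert ef.remove_problematic(_named_rma("CELLBOX"), exclusions=()).values.shape[0] == 3


def test_scale_to_reference_matches_means(default_pair):
    # exclusions disabled so nothing is removed after the scaling step
    t_tex, t_cb, _ = default_pair
    rma_tex, _ = ef.preprocess_platform(t_tex, exclusions=())
    rma_cb, rep_cb = ef.preprocess_platform(t_cb, reference=rma_tex, exclusions=())
    assert rma_cb.scaled_by == pytest.approx(rep_cb.scale_factor)
    assert np.mean(rma_cb.values.to_numpy()) == pytest.approx(np.mean(rma_tex.values.to_numpy()), rel=1e-9)


def test_scale_to_reference_halves_double_mean():
    from conftest import make_rma

    target = make_rma({"S1": [30.0], "S2": [10.0]}, groups={"S1": "flight", "S2": "ground"})
    reference = make_rma({"R1": [10.0], "R2": [10.0]}, groups={"R1": "flight", "R2": "ground"})
    out = ef.scale_to_reference(target, reference)
    assert out.scaled_by == pytest.approx(2.0)
    assert out.values.to_numpy().tolist() == [[15.0, 5.0]]


def test_scale_to_reference_rejects_zero_mean_target():
    from conftest import make_rma

    target = make_rma({"S1": [0.0], "S2": [0.0]}, groups={"S1": "flight", "S2": "ground"})
    reference = make_rma({"R1": [10.0], "R2": [10.0]}, groups={"R1": "flight", "R2": "ground"})
    with pytest.raises(ef.ValidationError):
        ef.scale_to_reference(target, reference)


# --- ladder-level properties ----------------------------------------------

def test_ladder_stages_are_idempotent_on_processed_tables(default_pair):
    _, t_cb, _ = default_pair
    table = ef.drop_unannotated(t_cb)
    table = ef.preprocess.impute_technical(table) if hasattr(ef, "preprocess") else table
    from exofoot.preprocess import impute_technical

    table = impute_technical(table)
    collapsed = ef.collapse_technical(table)
    combined = ef.combine_compartments(collapsed)
    filtered = ef.filter_missingness(combined)
    imputed = ef.impute_residual_mean(filtered)
    # re-running each stage on its own output changes nothing
    assert ef.collapse_technical(collapsed).values.equals(collapsed.values)
    assert ef.combine_compartments(combined).values.equals(combined.values)
    assert ef.filter_missingness(filtered).values.shape == filtered.values.shape
    assert ef.impute_residual_mean(imputed).values.equals(imputed.values)
    assert ef.drop_unannotated(table).values.equals(table.values)


def test_zero_noise_pipeline_recovers_planted_net_exactly(zero_noise_pair):
    t_tex, _, truth = zero_noise_pair
    rma, _ = ef.preprocess_platform(t_tex)
    gain = truth.platform_gain["TEXUS54"]
    for m in rma.values.index:
        for sid in rma.values.columns:
            cond = rma.samples.loc[sid, "condition"]
            cond = cond if rma.samples.loc[sid, "group"] == "flight" else "control"
            expected = gain * truth.base_net[m] * truth.effect(m, cond)
            assert rma.values.loc[m, sid] == pytest.approx(expected, rel=1e-9)


def test_fold_change_and_correlation_invariant_under_scaling(processed_pair):
    rma_tex, rma_cb, *_ = processed_pair
    recs = ef.differential_records(rma_cb, "flight_vs_ground", "two_sample")
    unscaled = rma_cb.copy()
    unscaled.values = unscaled.values * rma_cb.scaled_by
    unscaled.scaled_by = 1.0
    recs_unscaled = ef.differential_records(unscaled, "flight_vs_ground", "two_sample")
    for a, b in zip(recs, recs_unscaled):
        assert a.fc == pytest.approx(b.fc, rel=1e-9)
        assert a.raw_p == pytest.approx(b.raw_p, rel=1e-9)
    r1 = ef.correlation_matrix(rma_cb, cluster=False).r.to_numpy()
    r2 = ef.correlation_matrix(unscaled, cluster=False).r.to_numpy()
    assert np.allclose(r1, r2, atol=1e-9)
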