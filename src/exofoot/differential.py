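"""Per-metabolite differential analysis: signed fold change, t-tests, FDR bands, effect regions.

Fold change is the ratio of blank-subtracted means (flight / ground); it is
negative exactly when a metabolite flips between net production and net
consumption across the contrast ("inverted behaviour").  "Effect size"
denotes the magnitude |net RMA| of production or consumption, so a fold
change below -1 is an inversion with equal-or-larger effect.

Two test designs are supported: a Welch two-sample t-test of flight versus
ground biological samples (the long-duration design), and a one-sample
t-test of a single flight sample's technical replicates against the pooled
ground mean (the sounding-rocket design, where each condition has exactly
one biological sample).  Raw p values are converted to FDRs with the
Benjamini-Hochberg procedure and banded into "++" (FDR < 0.35), "+"
(0.35 <= FDR <= 0.50) and not-significant tiers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Constants, DEFAULT_CONSTANTS, DifferentialRecord, RMATable, ValidationError

CONTRAST_CONDITIONS = {
    "hypg_vs_ground": "hypg",
    "ug_vs_ground": "ug",
    "flight_vs_ground": None,  # all flight samples
}


def fold_change(flight_mean: float, ground_mean: float) -> float:
    """Signed fold change flight/ground; negative iff the means have opposite signs."""
    if ground_mean == 0:
        raise ZeroDivisionError("undefined fold change: ground mean is zero")
    return float(flight_mean) / float(ground_mean)


def test_two_sample(flight_values, ground_values) -> float:
    """Two-sided Welch t-test p-value between flight and ground values."""
    f = np.asarray(flight_values, dtype=float)
    g = np.asarray(ground_values, dtype=float)
    if f.size < 2 or g.size < 2:
        raise ValidationError("two-sample test needs >= 2 values per group")
    if f.std(ddof=1) == 0 and g.std(ddof=1) == 0:
        return 1.0 if f.mean() == g.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical data is a legal input
        return float(stats.ttest_ind(f, g, equal_var=False).pvalue)


def test_single_sample(flight_values, ground_mean: float) -> float:
    """Two-sided one-sample t-test of flight technical replicates against the ground mean."""
    f = np.asarray(flight_values, dtype=float)
    if f.size < 2:
        raise ValidationError("single-sample test needs >= 2 replicate values")
    if f.std(ddof=1) == 0:
        return 1.0 if f.mean() == ground_mean else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_1samp(f, popmean=float(ground_mean)).pvalue)


def estimate_fdr(raw_p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_band(fdr: float, constants: Constants = DEFAULT_CONSTANTS) -> str:
    """Two-tier significance band: '++' below the upper FDR bound, '+' up to the lower bound."""
    if fdr < constants.FDR_UPPER:
        return "pp"
    if fdr <= constants.FDR_LOWER:
        return "p"
    return "ns"


def classify_effect(fc: float, band: str, constants: Constants = DEFAULT_CONSTANTS) -> str:
    """Volcano-plot effect region; only significant (non-'ns') records are classified.

    Regions are open intervals: strong increase above FC_INCREASE, weak or
    inverted decrease strictly between FC_WEAK_LO and FC_WEAK_HI, strong
    inversion below FC_INVERT.
    """
    if band == "ns" or not np.isfinite(fc):
        return "unclassified"
    if fc > constants.FC_INCREASE:
        return "strong_increase"
    if constants.FC_WEAK_LO < fc < constants.FC_WEAK_HI:
        return "weak_or_inverted_decrease"
    if fc < constants.FC_INVERT:
        return "strong_inversion"
    return "unclassified"


def direction_of_change(flight_mean: float, ground_mean: float) -> int:
    """Sign of flight minus ground mean: more generation (+1) or stronger consumption (-1)."""
    return int(np.sign(flight_mean - ground_mean))


def _flight_matrix(table: RMATable, contrast: str, design: str):
    """Per-metabolite flight value matrix (columns entering the test) and the flight mean."""
    condition = CONTRAST_CONDITIONS[contrast]
    if design == "two_sample":
        cols = table.group_columns("flight")
        if condition is not None:
            cols = cols.intersection(table.condition_columns(condition))
        if len(cols) < 2:
            raise ValidationError(f"contrast {contrast!r} needs >= 2 flight samples for two_sample")
        vals = table.values[list(cols)]
        return vals, vals.mean(axis=1)
    if design == "single_sample":
        if table.replicate_values is None or table.replicate_meta is None:
            raise ValidationError("single_sample design needs replicate-level values on the table")
        meta = table.replicate_meta
        cols = meta.index[(meta["group"] == "flight") & (meta["condition"] == condition)]
        if len(cols) < 2:
            raise ValidationError(f"contrast {contrast!r} needs >= 2 technical replicates")
        vals = table.replicate_values[list(cols)]
        bio = meta.loc[cols, "biological_sample_id"].unique()
        flight_mean = table.values[[b for b in table.values.columns if b in set(bio)]].mean(axis=1)
        return vals, flight_mean
    raise ValidationError(f"unknown design {design!r}")


def differential_records(table: RMATable, contrast: str, design: str,
                         constants: Constants = DEFAULT_CONSTANTS) -> list:
    """Run the full differential analysis for one contrast.

    Returns one :class:`DifferentialRecord` per metabolite; FDR is estimated
    across the metabolite panel of this contrast.
    """
    if not table.blank_subtracted:
        raise ValidationError("differential analysis requires a blank-subtracted table")
    if contrast not in CONTRAST_CONDITIONS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    ground_cols = list(table.group_columns("ground"))
    if not ground_cols:
        raise ValidationError("table has no ground samples")
    ground = table.values[ground_cols]
    ground_mean = ground.mean(axis=1)
    ground_sd = ground.std(axis=1, ddof=1)

    flight_vals, flight_mean = _flight_matrix(table, contrast, design)

    raw_p = np.empty(len(table.values.index))
    for i, m in enumerate(table.values.index):
        fv = flight_vals.loc[m].to_numpy(dtype=float)
        if design == "two_sample":
            raw_p[i] = test_two_sample(fv, ground.loc[m].to_numpy(dtype=float))
        else:
            raw_p[i] = test_single_sample(fv, float(ground_mean.loc[m]))
    fdr = estimate_fdr(raw_p)

    records = []
    for i, m in enumerate(table.values.index):
        gm, fm = float(ground_mean.loc[m]), float(flight_mean.loc[m])
        band = assign_band(float(fdr[i]), constants)
        try:
            fc = fold_change(fm, gm)
            region = classify_effect(fc, band, constants)
        except ZeroDivisionError:
            fc, region = float("nan"), "unclassified"
        records.append(
            DifferentialRecord(
                metabolite_id=str(m),
                contrast=contrast,
                flight_mean=fm,
                ground_mean=gm,
                ground_sd=float(ground_sd.loc[m]),
                fc=fc,
                raw_p=float(raw_p[i]),
                fdr=float(fdr[i]),
                band=band,
                effect_region=region,
                direction=direction_of_change(fm, gm),
            )
        )
    return records


_BAND_MARK = {"pp": "++", "p": "+", "ns": ""}


def bar_export(table: RMATable, records, fdr_cutoff: float = 0.5) -> pd.DataFrame:
    """Mean +/- sample sd per group for the significant metabolites (volcano companion bars).

    One row per (metabolite, group); flight groups are split by condition.
    For a single-column flight group the sd falls back to the technical
    replicates when available.
    """
    keep = [r for r in records if r.fdr <= fdr_cutoff]
    rows = []
    for r in keep:
        condition = CONTRAST_CONDITIONS[r.contrast]
        groups = [("ground", list(table.group_columns("ground")))]
        fl = table.group_columns("flight")
        if condition is not None:
            fl = fl.intersection(table.condition_columns(condition))
        groups.append(("flight", list(fl)))
        for gname, cols in groups:
            vals = table.values.loc[r.metabolite_id, cols].to_numpy(dtype=float)
            if vals.size == 1 and table.replicate_values is not None and gname == "flight":
                meta = table.replicate_meta
                rep_cols = meta.index[meta["biological_sample_id"].isin(
                    table.samples.index[table.samples["condition"] == condition]
                )]
                rep = table.replicate_values.loc[r.metabolite_id, list(rep_cols)].to_numpy(dtype=float)
                sd = float(np.std(rep, ddof=1)) if rep.size > 1 else float("nan")
            else:
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
            rows.append(
                {
                    "metabolite_id": r.metabolite_id,
                    "contrast": r.contrast,
                    "group": gname,
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "band_mark": _BAND_MARK[r.band],
                }
            )
    return pd.DataFrame(rows, columns=["metabolite_id", "contrast", "group", "mean", "sd", "band_mark"])
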