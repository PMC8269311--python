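"""Preprocessing ladder: raw abundance tables to blank-subtracted net-RMA tables.

The documented order is fixed:

1. drop unannotated compounds;
2. impute missing technical replicates within replicate pairs (LOD rule);
3. collapse technical replicates to their mean per compartment;
4. combine compartments per biological sample by volume-weighted mean;
5. filter metabolites by group-wise missingness (two rules, see
   :func:`filter_missingness`);
6. mean-impute the few residual gaps within their group;
7. prepare the blank vector (mean of blank replicates, with a dataset-min
   fallback) and subtract it, turning abundances into signed net
   production/consumption;
8. optionally scale the table to the mean of a reference platform;
9. remove problematic metabolites (fixative/reference-mixture components,
   ubiquitous or non-human compounds).

Blank subtraction is placed after the missingness filter so that the
"below 50" clauses operate on raw signals, where a detection limit of 50
RMA units is meaningful.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .model import (
    Constants,
    DEFAULT_CONSTANTS,
    PreprocessReport,
    RMATable,
    RawAbundanceTable,
    ValidationError,
)

#: (name, reason, platform restriction or None) — the default exclusion list.
DEFAULT_EXCLUSIONS = (
    ("Sucrose", "fixative_component", "CELLBOX"),
    ("Nonadecane", "reference_mixture", None),
    ("Lactic acid", "uninterpretable_ubiquitous", None),
    ("Phosphoric acid", "uninterpretable_ubiquitous", None),
    ("Benzoic acid", "not_in_human_dbs", None),
    ("Diisopropylamine", "not_in_human_dbs", None),
    ("Edetic acid", "not_in_human_dbs", None),
    ("Oxamide", "not_in_human_dbs", None),
)


def _ismissing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or (
        isinstance(v, np.floating) and np.isnan(v)
    )


def drop_unannotated(table: RawAbundanceTable, report: PreprocessReport | None = None) -> RawAbundanceTable:
    """Remove compounds that were never matched to a reference spectrum."""
    keep = table.metabolites.index[table.metabolites["annotated"].astype(bool)]
    n_removed = len(table.metabolites) - len(keep)
    if report is not None:
        report.removed_unannotated += n_removed
    if len(keep) == 0:
        warnings.warn("no annotated metabolites remain after annotation filtering")
    return table.subset_metabolites(keep)


def impute_technical_pair(v1: float, v2: float, dataset_min: float, constants: Constants = DEFAULT_CONSTANTS):
    """Fill one missing value of a technical-replicate pair.

    If the surviving replicate is below the LOD the missing slot gets
    ``IMPUTE_FRACTION * dataset_min`` (the signal was plausibly censored);
    otherwise the surviving value is carried over.  Both-missing pairs are
    left to the group-level missingness filter and raise here.
    """
    miss1, miss2 = _ismissing(v1), _ismissing(v2)
    if miss1 and miss2:
        raise ValidationError("both technical replicates missing; handled by the missingness filter")
    if not miss1 and not miss2:
        return float(v1), float(v2)
    observed = float(v2 if miss1 else v1)
    if observed < constants.LOD:
        fill = constants.IMPUTE_FRACTION * float(dataset_min)
    else:
        fill = observed
    return (fill, observed) if miss1 else (observed, fill)


def impute_technical(table: RawAbundanceTable, constants: Constants = DEFAULT_CONSTANTS,
                     report: PreprocessReport | None = None, dataset_min: float | None = None) -> RawAbundanceTable:
    """Apply the pair-imputation rule to every size-2 replicate group of sample measurements."""
    if dataset_min is None:
        dataset_min = table.dataset_min()
    values = table.values.copy()
    meta = table.measurements
    sample_cols = table.sample_columns
    groups = meta.loc[sample_cols].groupby(["biological_sample_id", "compartment_id"], sort=False)
    for _, sub in groups:
        if len(sub) != 2:
            continue
        c1, c2 = list(sub.index)
        col1, col2 = values[c1].to_numpy(), values[c2].to_numpy()
        one_missing = np.isnan(col1) ^ np.isnan(col2)
        for i in np.nonzero(one_missing)[0]:
            new1, new2 = impute_technical_pair(col1[i], col2[i], dataset_min, constants)
            filled_low = (np.isnan(col1[i]) and col2[i] < constants.LOD) or (
                np.isnan(col2[i]) and col1[i] < constants.LOD
            )
            if report is not None:
                if filled_low:
                    report.imputed_lod += 1
                else:
                    report.imputed_carryover += 1
            col1[i], col2[i] = new1, new2
        values[c1], values[c2] = col1, col2
    return RawAbundanceTable(values, table.measurements, table.metabolites, table.platform)


def collapse_technical(table: RawAbundanceTable) -> RawAbundanceTable:
    """Average technical replicates per (biological sample, compartment).

    The mean runs over observed replicates; a collapsed cell is missing only
    if every replicate was missing.
    """
    meta = table.measurements
    key = meta["biological_sample_id"].astype(str) + "\x00" + meta["compartment_id"].astype(str)
    new_cols, new_meta_rows, new_vals = [], [], []
    seen = {}
    for cid in table.values.columns:
        k = key[cid]
        if k in seen:
            seen[k].append(cid)
        else:
            seen[k] = [cid]
    for k, cids in seen.items():
        first = meta.loc[cids[0]].copy()
        new_id = f"{first['biological_sample_id']}_{first['compartment_id']}"
        first["tech_rep_index"] = 0
        new_cols.append(new_id)
        new_meta_rows.append(first)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices are a legal outcome
            new_vals.append(np.nanmean(table.values[cids].to_numpy(), axis=1))
    values = pd.DataFrame(np.column_stack(new_vals), index=table.values.index, columns=new_cols)
    meta_out = pd.DataFrame(new_meta_rows)
    meta_out.index = pd.Index(new_cols, name="measurement_id")
    return RawAbundanceTable(values, meta_out, table.metabolites, table.platform)


def combine_compartments(table: RawAbundanceTable) -> RawAbundanceTable:
    """Volume-weighted mean over each biological sample's compartments."""
    meta = table.measurements
    new_cols, new_meta_rows, new_vals = [], [], []
    order = []
    for cid in table.values.columns:
        b = meta.loc[cid, "biological_sample_id"]
        if b not in order:
            order.append(b)
    for bio in order:
        cids = [c for c in table.values.columns if meta.loc[c, "biological_sample_id"] == bio]
        vols = meta.loc[cids, "recovered_volume"].to_numpy(dtype=float)
        if np.all(vols == 0):
            raise ValidationError(f"all-zero recovered volumes for sample {bio!r}")
        x = table.values[cids].to_numpy()
        if len(cids) == 1:
            combined = x[:, 0].copy()
        else:
            w = np.tile(vols, (x.shape[0], 1)).astype(float)
            w[np.isnan(x)] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                combined = np.nansum(np.nan_to_num(x) * np.nan_to_num(w), axis=1) / np.nansum(w, axis=1)
            combined[np.isnan(x).all(axis=1)] = np.nan
        first = meta.loc[cids[0]].copy()
        first["compartment_id"] = "combined"
        first["recovered_volume"] = float(np.sum(vols))
        first["tech_rep_index"] = 0
        new_cols.append(str(bio))
        new_meta_rows.append(first)
        new_vals.append(combined)
    values = pd.DataFrame(np.column_stack(new_vals), index=table.values.index, columns=new_cols)
    meta_out = pd.DataFrame(new_meta_rows)
    meta_out.index = pd.Index(new_cols, name="measurement_id")
    return RawAbundanceTable(values, meta_out, table.metabolites, table.platform)


def _rule_a_threshold(n: int, frac_num: int, frac_den: int) -> int:
    # paper counts (2 of 5 flight, 1 of 3 ground) generalized as ceil(frac * n)
    return max(1, math.ceil(n * frac_num / frac_den))


def filter_missingness(table: RawAbundanceTable, constants: Constants = DEFAULT_CONSTANTS,
                       report: PreprocessReport | None = None) -> RawAbundanceTable:
    """Group-wise missingness filter on the biological-sample level.

    Rule A: a metabolite is removed if a group's missing count reaches the
    group threshold (2 of 5 flight samples, 1 of 3 ground samples,
    generalized as ceil(2n/5) and ceil(n/3)) *and* every observed value in
    that same group is above the LOD (a censored low signal blocks the rule).
    Rule B (independent): removed if strictly more than half the values are
    missing in the flight group and in the ground group.
    """
    meta = table.measurements
    flight_cols = [c for c in table.values.columns if meta.loc[c, "group"] == "flight"]
    ground_cols = [c for c in table.values.columns if meta.loc[c, "group"] == "ground"]
    removed = []
    fvals = table.values[flight_cols].to_numpy() if flight_cols else np.empty((len(table.values), 0))
    gvals = table.values[ground_cols].to_numpy() if ground_cols else np.empty((len(table.values), 0))
    thr_f = _rule_a_threshold(len(flight_cols), 2, 5) if flight_cols else None
    thr_g = _rule_a_threshold(len(ground_cols), 1, 3) if ground_cols else None

    for i, m in enumerate(table.values.index):
        fmiss = int(np.isnan(fvals[i]).sum())
        gmiss = int(np.isnan(gvals[i]).sum())
        rule = None
        for vals, miss, thr in ((fvals[i], fmiss, thr_f), (gvals[i], gmiss, thr_g)):
            if thr is None or miss < thr:
                continue
            observed = vals[~np.isnan(vals)]
            if observed.size == 0 or np.all(observed > constants.LOD):
                rule = "A"
                break
        if rule is None and fvals.shape[1] and gvals.shape[1]:
            if fmiss * 2 > fvals.shape[1] and gmiss * 2 > gvals.shape[1]:
                rule = "B"
        if rule is not None:
            removed.append((m, rule))

    if report is not None:
        report.filtered_missingness.extend(removed)
    keep = [m for m in table.values.index if m not in {r[0] for r in removed}]
    return table.subset_metabolites(keep)


def impute_residual_mean(table: RawAbundanceTable, report: PreprocessReport | None = None) -> RawAbundanceTable:
    """Replace residual gaps with the within-group mean of the metabolite."""
    meta = table.measurements
    values = table.values.copy()
    for group in ("flight", "ground"):
        cols = [c for c in values.columns if meta.loc[c, "group"] == group]
        if not cols:
            continue
        block = values[cols].to_numpy()
        miss = np.isnan(block)
        if not miss.any():
            continue
        if miss.all(axis=1).any():
            raise ValidationError("a metabolite with a fully missing group survived the missingness filter")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(block, axis=1)
        block[miss] = np.take(means, np.nonzero(miss)[0])
        values[cols] = block
        if report is not None:
            report.imputed_mean += int(miss.sum())
    return RawAbundanceTable(values, table.measurements, table.metabolites, table.platform)


def prepare_blank(table: RawAbundanceTable, constants: Constants = DEFAULT_CONSTANTS,
                  dataset_min: float | None = None, report: PreprocessReport | None = None) -> pd.Series:
    """Per-metabolite blank value: mean of observed blank replicates.

    Mean-imputing partial gaps and then averaging equals the mean of the
    observed replicates.  An all-missing blank falls back to
    ``IMPUTE_FRACTION * dataset_min``.
    """
    blanks = table.values[table.blank_columns].to_numpy()
    if blanks.shape[1] == 0:
        raise ValidationError("table has no blank measurements")
    if dataset_min is None:
        dataset_min = table.dataset_min()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        blank = np.nanmean(blanks, axis=1)
    all_missing = np.isnan(blanks).all(axis=1)
    blank[all_missing] = constants.IMPUTE_FRACTION * float(dataset_min)
    if report is not None:
        report.imputed_blank += int(all_missing.sum())
    return pd.Series(blank, index=table.values.index, name="blank")


def subtract_blank(table: RawAbundanceTable, blank: pd.Series) -> RMATable:
    """Subtract the medium background; negatives mean net consumption."""
    if list(blank.index) != list(table.values.index):
        raise ValidationError("blank vector does not match the metabolite panel")
    meta = table.measurements
    sample_cols = list(table.sample_columns)
    values = table.values[sample_cols].sub(blank, axis=0)
    samples = meta.loc[sample_cols, ["platform", "group", "condition"]].copy()
    samples.index = pd.Index([meta.loc[c, "biological_sample_id"] for c in sample_cols], name="sample_id")
    values.columns = samples.index
    return RMATable(values=values, samples=samples, platform=table.platform, blank_subtracted=True)


def remove_problematic(table: RMATable, exclusions=DEFAULT_EXCLUSIONS,
                       report: PreprocessReport | None = None) -> RMATable:
    """Drop metabolites with no interpretable biological signal (fixed list)."""
    drop = {}
    for entry in exclusions:
        name, reason, restrict = (entry if len(entry) == 3 else (*entry, None))
        if restrict is not None and restrict != table.platform:
            continue
        if name in table.values.index:
            drop[name] = reason
    if report is not None:
        report.removed_problematic.extend(sorted(drop.items()))
    keep = [m for m in table.values.index if m not in drop]
    return table.subset_metabolites(keep)


def scale_to_reference(target: RMATable, reference: RMATable, report: PreprocessReport | None = None) -> RMATable:
    """Divide the target table by a scalar so its grand mean equals the reference's."""
    if not (target.blank_subtracted and reference.blank_subtracted):
        raise ValidationError("both tables must be blank-subtracted before scaling")
    t_mean = float(np.mean(target.values.to_numpy()))
    r_mean = float(np.mean(reference.values.to_numpy()))
    if t_mean == 0:
        raise ValidationError("degenerate scaling: target grand mean is zero")
    k = t_mean / r_mean
    if k <= 0:
        raise ValidationError(f"degenerate scaling: non-positive factor {k}")
    out = target.copy()
    out.values = out.values / k
    if out.replicate_values is not None:
        out.replicate_values = out.replicate_values / k
    out.scaled_by = k
    if report is not None:
        report.scale_factor = k
    return out


def preprocess_platform(raw: RawAbundanceTable, constants: Constants = DEFAULT_CONSTANTS,
                        reference: RMATable | None = None, exclusions=DEFAULT_EXCLUSIONS,
                        keep_replicates: bool = True):
    """Run the full ladder; returns ``(RMATable, PreprocessReport)``.

    With ``keep_replicates`` the blank-subtracted technical-replicate-level
    matrix is attached to the result (needed by the single-sample t-test of
    the rocket-flight design).
    """
    report = PreprocessReport()
    table = drop_unannotated(raw, report)
    dataset_min = table.dataset_min()
    report.dataset_min = dataset_min
    table = impute_technical(table, constants, report, dataset_min)
    imputed_reps = table  # replicate-level, after pair imputation
    table = collapse_technical(table)
    table = combine_compartments(table)
    table = filter_missingness(table, constants, report)
    table = impute_residual_mean(table, report)
    blank = prepare_blank(imputed_reps.subset_metabolites(table.values.index), constants, dataset_min, report)
    rma = subtract_blank(table, blank)
    if keep_replicates:
        rep_cols = list(imputed_reps.sample_columns)
        rep_vals = imputed_reps.values.loc[table.values.index, rep_cols].sub(blank, axis=0)
        rma.replicate_values = rep_vals
        rma.replicate_meta = imputed_reps.measurements.loc[rep_cols]
    if reference is not None:
        rma = scale_to_reference(rma, reference, report)
    rma = remove_problematic(rma, exclusions, report)
    return rma, report
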