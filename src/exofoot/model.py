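"""Domain types for GC-MS exometabolome footprinting tables.

Relative metabolite abundance (RMA) is a dimensionless, internal-standard
normalized GC-MS signal.  Raw tables hold non-negative RMA values per
metabolite and measurement (technical replicate of a compartment of a
biological sample, or a medium blank); missing entries are ``NaN`` in memory
and an empty cell / ``NA`` on disk.  Zero is a real measurement, never
missing.  After replicate collapsing, volume-weighted compartment
combination and blank subtraction the table becomes an :class:`RMATable`
whose signed entries are net production (>0) / net consumption (<0) of the
cultured cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORMS = frozenset({"TEXUS54", "CELLBOX"})
ROLES = frozenset({"sample", "blank"})
GROUPS = frozenset({"flight", "ground", "none"})
CONDITIONS = frozenset({"hypg", "ug", "longterm", "control", "none"})
EXCLUSION_REASONS = frozenset(
    {"fixative_component", "reference_mixture", "uninterpretable_ubiquitous", "not_in_human_dbs", "none"}
)

#: Columns of the measurement-metadata frame, in canonical order.
MEASUREMENT_COLUMNS = (
    "platform",
    "role",
    "group",
    "condition",
    "biological_sample_id",
    "compartment_id",
    "recovered_volume",
    "tech_rep_index",
)

METABOLITE_COLUMNS = ("name", "annotated", "excluded_reason")


class ValidationError(ValueError):
    """A table or metadata frame violates a domain invariant."""


class FormatError(ValueError):
    """A file cannot be parsed into the expected layout."""


@dataclass(frozen=True)
class Constants:
    """Pipeline thresholds; defaults are the study's values.

    LOD
        Raw-signal limit of detection, in RMA units.  Signals below it are
        treated as censored.
    IMPUTE_FRACTION
        Fraction of the dataset-wide minimum observed signal used to fill a
        missing technical replicate whose partner is below the LOD.
    FDR_UPPER / FDR_LOWER
        Boundaries of the two significance bands: "++" below FDR_UPPER,
        "+" between FDR_UPPER and FDR_LOWER inclusive.
    FC_INCREASE, FC_WEAK_LO/HI, FC_INVERT
        Fold-change boundaries of the effect regions (strong increase above
        FC_INCREASE; weak or inverted decrease strictly inside
        (FC_WEAK_LO, FC_WEAK_HI); strong inversion below FC_INVERT).
    """

    LOD: float = 50.0
    IMPUTE_FRACTION: float = 1.0 / 5.0
    FDR_UPPER: float = 0.35
    FDR_LOWER: float = 0.50
    FC_INCREASE: float = 2.0
    FC_WEAK_LO: float = -0.5
    FC_WEAK_HI: float = 0.5
    FC_INVERT: float = -1.0

    def __post_init__(self) -> None:
        if not (0 < self.FDR_UPPER < self.FDR_LOWER <= 1):
            raise ValidationError(
                f"require 0 < FDR_UPPER < FDR_LOWER <= 1, got {self.FDR_UPPER}, {self.FDR_LOWER}"
            )
        if self.LOD < 0 or self.IMPUTE_FRACTION <= 0:
            raise ValidationError("LOD must be >= 0 and IMPUTE_FRACTION > 0")

    def replace(self, **kwargs) -> "Constants":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONSTANTS = Constants()


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def validate_measurements(meta: pd.DataFrame) -> None:
    """Check a measurement-metadata frame (indexed by measurement id)."""
    _require(meta.index.is_unique, "duplicate measurement ids in metadata")
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in meta.columns]
    _require(not missing_cols, f"metadata lacks columns: {missing_cols}")
    _require(meta["platform"].isin(PLATFORMS).all(), "unknown platform in metadata")
    _require(meta["role"].isin(ROLES).all(), "unknown role in metadata")
    _require(meta["group"].isin(GROUPS).all(), "unknown group in metadata")
    _require(meta["condition"].isin(CONDITIONS).all(), "unknown condition in metadata")
    blanks = meta["role"] == "blank"
    _require(
        (meta.loc[blanks, "group"] == "none").all() and (meta.loc[blanks, "condition"] == "none").all(),
        "blank measurements must have group=none and condition=none",
    )
    _require((meta["recovered_volume"] > 0).all(), "recovered_volume must be > 0")
    key = meta[["biological_sample_id", "compartment_id", "tech_rep_index"]]
    _require(not key.duplicated().any(), "(biological_sample_id, compartment_id, tech_rep_index) must be unique")


@dataclass
class RawAbundanceTable:
    """Metabolite x measurement matrix of raw RMA signals.

    ``values`` is indexed by metabolite id with one column per measurement
    id; entries are >= 0 or NaN (missing).  ``measurements`` is indexed by
    measurement id, ``metabolites`` by metabolite id.
    """

    values: pd.DataFrame
    measurements: pd.DataFrame
    metabolites: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.platform in PLATFORMS, f"unknown platform {self.platform!r}")
        _require(self.values.index.is_unique, "duplicate metabolite ids")
        _require(self.values.columns.is_unique, "duplicate measurement ids")
        _require(
            list(self.values.columns) == list(self.measurements.index),
            "measurement metadata does not match table columns",
        )
        _require(
            list(self.values.index) == list(self.metabolites.index),
            "metabolite metadata does not match table rows",
        )
        validate_measurements(self.measurements)
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("raw abundance values must be non-negative")

    # -- convenience views -------------------------------------------------
    @property
    def sample_columns(self) -> pd.Index:
        return self.measurements.index[self.measurements["role"] == "sample"]

    @property
    def blank_columns(self) -> pd.Index:
        return self.measurements.index[self.measurements["role"] == "blank"]

    def dataset_min(self) -> float:
        """Lowest observed raw signal over the whole platform dataset (blanks included)."""
        vals = self.values.to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            raise ValidationError("cannot compute dataset minimum: no observed values")
        return float(np.nanmin(vals))

    def subset_metabolites(self, ids) -> "RawAbundanceTable":
        ids = list(ids)
        return RawAbundanceTable(
            values=self.values.loc[ids],
            measurements=self.measurements,
            metabolites=self.metabolites.loc[ids],
            platform=self.platform,
        )

    def subset_measurements(self, ids) -> "RawAbundanceTable":
        ids = list(ids)
        return RawAbundanceTable(
            values=self.values[ids],
            measurements=self.measurements.loc[ids],
            metabolites=self.metabolites,
            platform=self.platform,
        )

    def copy(self) -> "RawAbundanceTable":
        return RawAbundanceTable(
            self.values.copy(), self.measurements.copy(), self.metabolites.copy(), self.platform
        )


@dataclass
class RMATable:
    """Metabolite x biological-sample matrix of net RMA values.

    After blank subtraction entries are signed: positive = net production
    into the supernatant, negative = net consumption from the medium.
    ``samples`` is indexed by biological sample id with columns
    ``platform, group, condition``.  ``replicate_values`` optionally keeps
    the blank-subtracted technical-replicate-level matrix (needed by the
    single-sample t-test on rocket-flight technical replicates), with
    ``replicate_meta`` its measurement metadata.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str
    blank_subtracted: bool = False
    scaled_by: float = 1.0
    replicate_values: pd.DataFrame | None = None
    replicate_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.platform in PLATFORMS, f"unknown platform {self.platform!r}")
        _require(self.values.columns.is_unique, "duplicate biological sample ids")
        _require(
            list(self.values.columns) == list(self.samples.index),
            "sample metadata does not match table columns",
        )
        _require(self.samples["group"].isin(GROUPS).all(), "unknown group in sample metadata")
        _require(self.scaled_by > 0, "scaled_by must be > 0")
        if self.replicate_values is not None:
            _require(
                list(self.replicate_values.index) == list(self.values.index),
                "replicate_values rows must match the collapsed table",
            )

    def group_columns(self, group: str) -> pd.Index:
        return self.samples.index[self.samples["group"] == group]

    def condition_columns(self, condition: str) -> pd.Index:
        return self.samples.index[self.samples["condition"] == condition]

    def subset_metabolites(self, ids) -> "RMATable":
        ids = list(ids)
        return RMATable(
            values=self.values.loc[ids],
            samples=self.samples,
            platform=self.platform,
            blank_subtracted=self.blank_subtracted,
            scaled_by=self.scaled_by,
            replicate_values=None if self.replicate_values is None else self.replicate_values.loc[ids],
            replicate_meta=self.replicate_meta,
        )

    def drop_samples(self, ids) -> "RMATable":
        ids = set(ids)
        keep = [c for c in self.values.columns if c not in ids]
        rep_vals, rep_meta = self.replicate_values, self.replicate_meta
        if rep_vals is not None and rep_meta is not None:
            keep_rep = rep_meta.index[~rep_meta["biological_sample_id"].isin(ids)]
            rep_vals = rep_vals[list(keep_rep)]
            rep_meta = rep_meta.loc[keep_rep]
        return RMATable(
            values=self.values[keep],
            samples=self.samples.loc[keep],
            platform=self.platform,
            blank_subtracted=self.blank_subtracted,
            scaled_by=self.scaled_by,
            replicate_values=rep_vals,
            replicate_meta=rep_meta,
        )

    def copy(self) -> "RMATable":
        return RMATable(
            self.values.copy(),
            self.samples.copy(),
            self.platform,
            self.blank_subtracted,
            self.scaled_by,
            None if self.replicate_values is None else self.replicate_values.copy(),
            None if self.replicate_meta is None else self.replicate_meta.copy(),
        )


@dataclass
class DifferentialRecord:
    """Per-metabolite differential result for one contrast."""

    metabolite_id: str
    contrast: str  # hypg_vs_ground | ug_vs_ground | flight_vs_ground
    flight_mean: float
    ground_mean: float
    ground_sd: float
    fc: float
    raw_p: float
    fdr: float
    band: str  # pp | p | ns
    effect_region: str  # strong_increase | weak_or_inverted_decrease | strong_inversion | unclassified
    direction: int  # -1 | 0 | +1


@dataclass
class ClusterSet:
    """Conserved correlation clusters: metabolite groups with strong mutual |r| in both datasets."""

    clusters: list  # of (tuple(sorted ids), mean |r| in dataset 1, mean |r| in dataset 2)
    threshold: float
    min_size: int = 2

    def memberships(self) -> dict:
        out = {}
        for k, (ids, _, _) in enumerate(self.clusters, start=1):
            for m in ids:
                out[m] = k
        return out


@dataclass
class CrossPlatformRecord:
    """Shared-metabolite record of the two-platform fold-change projection."""

    metabolite_id: str
    fc_short: float
    fc_long: float
    quadrant: str  # upper_left | upper_right | lower_left | lower_right | center
    inverted_short: bool
    inverted_long: bool
    concordant: bool
    band_short: str
    band_long: str
    band_hypg: str
    cluster_id: int | None = None


@dataclass
class PreprocessReport:
    """Audit trail of the preprocessing ladder."""

    removed_unannotated: int = 0
    imputed_lod: int = 0
    imputed_carryover: int = 0
    filtered_missingness: list = field(default_factory=list)  # (metabolite_id, rule)
    imputed_mean: int = 0
    imputed_blank: int = 0
    removed_problematic: list = field(default_factory=list)  # (metabolite_id, reason)
    scale_factor: float = 1.0
    dataset_min: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "removed_unannotated": self.removed_unannotated,
            "imputed_lod": self.imputed_lod,
            "imputed_carryover": self.imputed_carryover,
            "filtered_missingness": [list(t) for t in self.filtered_missingness],
            "imputed_mean": self.imputed_mean,
            "imputed_blank": self.imputed_blank,
            "removed_problematic": [list(t) for t in self.removed_problematic],
            "scale_factor": self.scale_factor,
            "dataset_min": self.dataset_min,
        }
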