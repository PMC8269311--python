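"""Readers and writers for abundance tables, metadata sidecars and result records.

On-disk conventions: abundance tables are UTF-8 TSV/CSV with the header row
holding measurement ids and the first column metabolite ids; an empty cell
or the sentinel ``NA`` is a missing value.  Measurement metadata travels in
a TSV/CSV or JSON sidecar keyed by measurement id, metabolite annotation in
an optional second sidecar.  Result records round-trip losslessly at 12
significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    MEASUREMENT_COLUMNS,
    METABOLITE_COLUMNS,
    ClusterSet,
    CrossPlatformRecord,
    DifferentialRecord,
    FormatError,
    RawAbundanceTable,
    ValidationError,
)

MISSING_SENTINELS = ["", "NA"]
FLOAT_FORMAT = "%.12g"


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_measurement_meta(meta_path) -> pd.DataFrame:
    meta_path = Path(meta_path)
    if meta_path.suffix.lower() == ".json":
        with open(meta_path) as fh:
            payload = json.load(fh)
        meta = pd.DataFrame.from_dict(payload, orient="index")
        meta.index.name = "measurement_id"
    else:
        meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), index_col=0, dtype={0: str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"measurement metadata lacks columns: {missing}")
    meta["recovered_volume"] = meta["recovered_volume"].astype(float)
    meta["tech_rep_index"] = meta["tech_rep_index"].astype(int)
    return meta[list(MEASUREMENT_COLUMNS)]


def read_metabolite_meta(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype={0: str})
    missing = [c for c in METABOLITE_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metabolite metadata lacks columns: {missing}")
    meta["annotated"] = meta["annotated"].astype(bool)
    meta["excluded_reason"] = meta["excluded_reason"].fillna("none")
    return meta[list(METABOLITE_COLUMNS)]


def read_abundance_table(path, meta_path, metabolite_meta_path=None) -> RawAbundanceTable:
    """Read a raw abundance TSV/CSV plus its metadata sidecar(s).

    Without a metabolite sidecar every metabolite is taken as annotated
    (name = id, no exclusion reason).
    """
    path = Path(path)
    values = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=MISSING_SENTINELS,
        keep_default_na=False,
        dtype={0: str},
    )
    if values.columns.duplicated().any():
        raise FormatError(f"duplicate measurement ids in {path.name}")
    if values.index.duplicated().any():
        raise FormatError(f"duplicate metabolite ids in {path.name}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value in {path.name}: {exc}") from exc

    meta = read_measurement_meta(meta_path)
    if set(meta.index) != set(values.columns):
        raise ValidationError(
            f"metadata measurements do not match table columns "
            f"({len(meta)} metadata rows vs {values.shape[1]} columns)"
        )
    meta = meta.loc[list(values.columns)]

    if metabolite_meta_path is not None:
        metab = read_metabolite_meta(metabolite_meta_path)
        if set(metab.index) != set(values.index):
            raise ValidationError("metabolite metadata does not match table rows")
        metab = metab.loc[list(values.index)]
    else:
        metab = pd.DataFrame(
            {"name": values.index, "annotated": True, "excluded_reason": "none"},
            index=values.index,
        )

    platforms = meta["platform"].unique()
    if len(platforms) != 1:
        raise ValidationError(f"a raw table must hold a single platform, got {list(platforms)}")
    return RawAbundanceTable(values=values, measurements=meta, metabolites=metab, platform=platforms[0])


def write_abundance_table(table: RawAbundanceTable, path, meta_path, metabolite_meta_path=None) -> None:
    path = Path(path)
    table.values.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=FLOAT_FORMAT)
    meta_path = Path(meta_path)
    if meta_path.suffix.lower() == ".json":
        payload = {str(i): row.to_dict() for i, row in table.measurements.iterrows()}
        with open(meta_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        table.measurements.to_csv(meta_path, sep=_sep_for(meta_path), index_label="measurement_id")
    if metabolite_meta_path is not None:
        table.metabolites.to_csv(
            Path(metabolite_meta_path), sep=_sep_for(Path(metabolite_meta_path)), index_label="metabolite_id"
        )


# --- result records -------------------------------------------------------

_RECORD_TYPES = {
    "DifferentialRecord": DifferentialRecord,
    "CrossPlatformRecord": CrossPlatformRecord,
}


def records_to_frame(records) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if rows:
        return pd.DataFrame(rows, columns=list(rows[0].keys()))
    # empty: infer header from an empty record class is not possible; emit no columns
    return pd.DataFrame()


def write_records(records, path, record_type=None) -> None:
    """Write differential / cross-platform records as a stable-column TSV.

    For an empty list the record class (or ``record_type`` name) must be
    given to emit the header row.
    """
    path = Path(path)
    if records:
        frame = records_to_frame(records)
    else:
        cls = record_type
        if isinstance(cls, str):
            cls = _RECORD_TYPES[cls]
        if cls is None:
            raise ValidationError("empty record list needs record_type to write a header")
        frame = pd.DataFrame(columns=[f.name for f in dataclasses.fields(cls)])
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FORMAT)


def _coerce(value, typ):
    if typ in ("int | None", "typing.Optional[int]"):
        return None if (value is None or (isinstance(value, float) and np.isnan(value))) else int(value)
    return value


def read_records(path, record_cls):
    """Read a record TSV back into dataclass instances (round-trip of write_records)."""
    frame = pd.read_csv(Path(path), sep="\t", na_values=MISSING_SENTINELS, keep_default_na=True)
    fields = dataclasses.fields(record_cls)
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in fields:
            v = row[f.name]
            if f.type in ("int",):
                v = int(v)
            elif f.type in ("float",):
                v = float(v)
            elif f.type in ("bool",):
                v = bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"
            elif f.type in ("str",):
                v = str(v)
            else:
                v = _coerce(v, f.type)
            kwargs[f.name] = v
        out.append(record_cls(**kwargs))
    return out


def write_cluster_set(cs: ClusterSet, path) -> None:
    rows = [
        {
            "cluster_id": k,
            "metabolites": ";".join(ids),
            "mean_abs_r_dataset1": r1,
            "mean_abs_r_dataset2": r2,
            "threshold": cs.threshold,
        }
        for k, (ids, r1, r2) in enumerate(cs.clusters, start=1)
    ]
    frame = pd.DataFrame(
        rows, columns=["cluster_id", "metabolites", "mean_abs_r_dataset1", "mean_abs_r_dataset2", "threshold"]
    )
    frame.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_cluster_set(path) -> ClusterSet:
    frame = pd.read_csv(Path(path), sep="\t")
    clusters = [
        (tuple(str(r.metabolites).split(";")), float(r.mean_abs_r_dataset1), float(r.mean_abs_r_dataset2))
        for r in frame.itertuples()
    ]
    threshold = float(frame["threshold"].iloc[0]) if len(frame) else float("nan")
    return ClusterSet(clusters=clusters, threshold=threshold)


def write_matrix(frame: pd.DataFrame, path, index_label="id") -> None:
    frame.to_csv(Path(path), sep="\t", na_rep="NA", float_format=FLOAT_FORMAT, index_label=index_label)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
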