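import numpy as np
import pandas as pd
import pytest

import exofoot as ef


def make_raw(values, meta_rows, platform="CELLBOX", annotated=None):
    """Build a RawAbundanceTable from a dict of columns and metadata tuples.

    ``values``: {measurement_id: list of floats (np.nan = missing)}
    ``meta_rows``: {measurement_id: (role, group, condition, bio_id, comp_id, volume, rep)}
    """
    frame = pd.DataFrame(values)
    n = frame.shape[0]
    frame.index = pd.Index([f"M{i + 1}" for i in range(n)], name="metabolite_id")
    meta = pd.DataFrame(
        [(platform, *meta_rows[c]) for c in frame.columns],
        index=pd.Index(list(frame.columns), name="measurement_id"),
        columns=[
            "platform", "role", "group", "condition",
            "biological_sample_id", "compartment_id", "recovered_volume", "tech_rep_index",
        ],
    )
    if annotated is None:
        annotated = [True] * n
    metab = pd.DataFrame(
        {"name": frame.index, "annotated": annotated, "excluded_reason": "none"},
        index=frame.index,
    )
    return ef.RawAbundanceTable(values=frame, measurements=meta, metabolites=metab, platform=platform)


def make_rma(values, groups, platform="CELLBOX", conditions=None, metabolite_ids=None):
    """Build a blank-subtracted RMATable from a dict of sample columns."""
    frame = pd.DataFrame(values)
    n = frame.shape[0]
    ids = metabolite_ids or [f"M{i + 1}" for i in range(n)]
    frame.index = pd.Index(ids, name="metabolite_id")
    if conditions is None:
        conditions = {c: ("longterm" if groups[c] == "flight" else "control") for c in frame.columns}
    samples = pd.DataFrame(
        {
            "platform": platform,
            "group": [groups[c] for c in frame.columns],
            "condition": [conditions[c] for c in frame.columns],
        },
        index=pd.Index(list(frame.columns), name="sample_id"),
    )
    return ef.RMATable(values=frame, samples=samples, platform=platform, blank_subtracted=True)


@pytest.fixture(scope="session")
def default_pair():
    return ef.generate_pair(seed=7)


@pytest.fixture(scope="session")
def zero_noise_pair():
    return ef.generate_pair(
        seed=7, noise_cv=0.0, missing_below_lod_prob=0.0, with_blocks=False, with_outlier=False
    )


@pytest.fixture(scope="session")
def processed_pair(default_pair):
    t_tex, t_cb, truth = default_pair
    rma_tex, rep_tex = ef.preprocess_platform(t_tex)
    rma_cb, rep_cb = ef.preprocess_platform(t_cb, reference=rma_tex)
    return rma_tex, rma_cb, rep_tex, rep_cb, truth
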