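"""Cross-platform fold-change projection, quadrant/concordance classification, band summary.

Shared metabolites are projected onto a plane with the long-term (ISS)
fold change on the horizontal axis and the short-term (rocket, µg vs
ground) fold change on the vertical axis.  Quadrants are defined on effect
strength s = |FC| — the magnitude of net production or consumption —
because metabolites with a negative fold change invert their direction of
change and are an exception to the plain quadrant reading; inversion is
carried as separate flags rather than discarding those metabolites.  The
center region holds metabolites without a strong effect in either
experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ClusterSet, CrossPlatformRecord, DifferentialRecord, ValidationError

_BAND_MARK = {"pp": "++", "p": "+", "ns": ""}


def shared_metabolites(panel1, panel2) -> list:
    """Sorted intersection of two metabolite id lists."""
    return sorted(set(panel1) & set(panel2))


def classify_quadrant(fc_short: float, fc_long: float,
                      center_lo: float = 0.5, center_hi: float = 2.0):
    """Quadrant on effect strength |fc|, plus per-axis inversion flags.

    Returns ``(quadrant, inverted_short, inverted_long)``.  Center when both
    strengths lie inside [center_lo, center_hi]; otherwise upper/lower by
    the short-term strength against 1, right/left by the long-term strength
    against 1.
    """
    if not (center_lo < 1 < center_hi):
        raise ValidationError("center interval must straddle 1")
    s_short, s_long = abs(fc_short), abs(fc_long)
    inverted_short, inverted_long = fc_short < 0, fc_long < 0
    if center_lo <= s_short <= center_hi and center_lo <= s_long <= center_hi:
        return "center", inverted_short, inverted_long
    vert = "upper" if s_short > 1 else "lower"
    horiz = "right" if s_long > 1 else "left"
    return f"{vert}_{horiz}", inverted_short, inverted_long


def concordance(direction_short: int, direction_long: int) -> bool:
    """True iff the direction of change is the same and nonzero on both platforms."""
    return direction_short == direction_long and direction_short != 0


def cross_platform_records(records_short, records_long, records_hypg=None,
                           cluster_set: ClusterSet | None = None,
                           center_lo: float = 0.5, center_hi: float = 2.0) -> list:
    """Join the per-platform differential records on their shared metabolites."""
    by_short = {r.metabolite_id: r for r in records_short}
    by_long = {r.metabolite_id: r for r in records_long}
    by_hypg = {r.metabolite_id: r for r in (records_hypg or [])}
    memberships = cluster_set.memberships() if cluster_set is not None else {}
    out = []
    for m in shared_metabolites(by_short, by_long):
        rs, rl = by_short[m], by_long[m]
        quadrant, inv_s, inv_l = classify_quadrant(rs.fc, rl.fc, center_lo, center_hi)
        rh = by_hypg.get(m)
        out.append(
            CrossPlatformRecord(
                metabolite_id=m,
                fc_short=rs.fc,
                fc_long=rl.fc,
                quadrant=quadrant,
                inverted_short=inv_s,
                inverted_long=inv_l,
                concordant=concordance(rs.direction, rl.direction),
                band_short=rs.band,
                band_long=rl.band,
                band_hypg=rh.band if rh is not None else "ns",
                cluster_id=memberships.get(m),
            )
        )
    return out


def band_summary(records_hypg, records_short, records_long,
                 cluster_set: ClusterSet | None = None,
                 metabolites=None) -> pd.DataFrame:
    """Band-mark table per metabolite and contrast, grouped by conserved cluster.

    One row per metabolite with '++'/'+'/'' marks for the hypergravity,
    short-term microgravity and long-term contrasts; metabolites outside any
    cluster form the trailing ungrouped section.
    """
    marks = {}
    for key, records in (("hypg", records_hypg), ("short", records_short), ("long", records_long)):
        marks[key] = {r.metabolite_id: _BAND_MARK[r.band] for r in (records or [])}
    if metabolites is None:
        pool = set()
        for d in marks.values():
            pool |= set(d)
        metabolites = sorted(pool)
    memberships = cluster_set.memberships() if cluster_set is not None else {}
    rows = []
    for m in metabolites:
        rows.append(
            {
                "cluster_id": memberships.get(m, 0),
                "metabolite_id": m,
                "hypg": marks["hypg"].get(m, ""),
                "ug_short": marks["short"].get(m, ""),
                "longterm": marks["long"].get(m, ""),
            }
        )
    frame = pd.DataFrame(rows, columns=["cluster_id", "metabolite_id", "hypg", "ug_short", "longterm"])
    frame = frame.sort_values(
        by=["cluster_id", "metabolite_id"],
        key=lambda col: col.map(lambda v: (v == 0, v)) if col.name == "cluster_id" else col,
        kind="stable",
    ).reset_index(drop=True)
    frame["cluster_id"] = frame["cluster_id"].replace(0, pd.NA)
    return frame


def records_frame(records) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in records])
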