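"""Linking FCN attributes to HUC-12 subwatersheds.

Multiple FCNs can intersect one HUC-12. Each HUC-12 is characterized by the
*longest* (total stream km) historical and current FCN intersecting it; the
change in habitat composition between those two patches provides the
percent-change predictors. Condition scores are summarized per HUC-12: HWI
and local hydrologic regulation as length-weighted means over the HUC-12's
reaches, upstream dam density/storage taken at the HUC-12 outlet (the reach
with the largest drainage area).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delineation import FCN, percent_change
from .errors import UnknownReachError
from .habitat import FCNHabitatSummary, sanitize_class
from .network import RiverNetwork

logger = logging.getLogger(__name__)

CONDITION_FIELDS = ("hwi", "local_hydro_reg")
OUTLET_FIELDS = ("upstream_dam_density", "upstream_dam_storage")


def longest_fcn_per_huc12(fcns: Sequence[FCN], net: RiverNetwork) -> dict[str, str]:
    """Map each HUC-12 to the fcn_id of its longest intersecting FCN.

    Ties are broken by the smaller fcn_id (logged). HUC-12s with no reaches
    simply do not appear.
    """
    huc = net.frame["huc12_id"]
    best: dict[str, FCN] = {}
    for f in sorted(fcns, key=lambda f: f.fcn_id):
        for h in set(huc.loc[list(f.reach_ids)]):
            cur = best.get(h)
            if cur is None or f.total_length_km > cur.total_length_km:
                best[h] = f
            elif f.total_length_km == cur.total_length_km and f.fcn_id != cur.fcn_id:
                logger.info(
                    "HUC-12 %s: length tie between FCN %s and %s; keeping %s",
                    h, cur.fcn_id, f.fcn_id, min(cur.fcn_id, f.fcn_id),
                )
    return {h: f.fcn_id for h, f in best.items()}


def habitat_change_predictors(
    hist: FCNHabitatSummary, curr: FCNHabitatSummary
) -> dict[str, float]:
    """Historic→current habitat change variables for one HUC-12.

    Per habitat class: ``<class>_km_pctchg`` = 100 × (curr − hist)/hist km
    (negative = loss; undefined when the class was absent historically, in
    which case the ``<class>_presence_chg`` ∈ {−1, 0, +1} carries the gain
    signal and the percent change is left missing). Also emits the
    total-length percent change (``length_km_pctchg``) and the change in the
    rarity-weighted-richness z-score (``rwr_z_chg``).
    """
    out: dict[str, float] = {}
    classes = sorted(set(hist.class_lengths) | set(curr.class_lengths))
    for c in classes:
        h_km = float(hist.class_lengths.get(c, 0.0))
        c_km = float(curr.class_lengths.get(c, 0.0))
        key = sanitize_class(c)
        if h_km > 0:
            out[f"{key}_km_pctchg"] = percent_change(h_km, c_km)
        else:
            out[f"{key}_km_pctchg"] = np.nan
            if c_km > 0:
                logger.info("class %s gained from zero baseline; pct change undefined", c)
        out[f"{key}_presence_chg"] = float(
            int(c in curr.presence) - int(c in hist.presence)
        )
    # waterbody classes can be present with no class length entry
    for c in sorted((set(hist.presence) | set(curr.presence)) - set(classes)):
        out[f"{sanitize_class(c)}_presence_chg"] = float(
            int(c in curr.presence) - int(c in hist.presence)
        )
    out["length_km_pctchg"] = percent_change(hist.total_length_km, curr.total_length_km)
    out["rwr_z_chg"] = float(curr.rwr_z - hist.rwr_z)
    return out


def length_weighted_condition(
    net: RiverNetwork, huc12_id: str, fields: Sequence[str] = CONDITION_FIELDS
) -> dict[str, float]:
    """Length-weighted mean condition scores over a HUC-12's reaches.

    Missing values are skipped with the weights renormalized over the
    non-missing reaches; all-missing gives NaN with a log notice — missing
    condition never silently becomes zero.
    """
    df = net.frame
    sub = df[df["huc12_id"] == huc12_id]
    if sub.empty:
        raise UnknownReachError(f"HUC-12 {huc12_id!r} has no reaches")
    out = {}
    w = sub["length_km"].to_numpy(dtype=float)
    for f in fields:
        v = sub[f].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.any():
            logger.info("HUC-12 %s: all %s values missing", huc12_id, f)
            out[f] = np.nan
        else:
            out[f] = float(np.average(v[ok], weights=w[ok]))
    return out


def outlet_upstream_metrics(
    net: RiverNetwork, huc12_id: str, fields: Sequence[str] = OUTLET_FIELDS
) -> dict[str, float]:
    """Upstream-accumulated metrics at the HUC-12 outlet.

    The outlet is the reach with maximal drainage area in the HUC-12 (ties
    broken by smallest reach_id).
    """
    df = net.frame
    sub = df[df["huc12_id"] == huc12_id]
    if sub.empty:
        raise UnknownReachError(f"HUC-12 {huc12_id!r} has no reaches")
    area = sub["drainage_area_km2"]
    outlet = min(area.index[area == area.max()])
    return {f: float(sub.at[outlet, f]) for f in fields}


def build_huc12_table(
    net: RiverNetwork,
    fcns_hist: Sequence[FCN],
    fcns_curr: Sequence[FCN],
    summaries_hist: Sequence[FCNHabitatSummary],
    summaries_curr: Sequence[FCNHabitatSummary],
    centroids: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per HUC-12: longest-FCN linkage, change predictors, condition.

    ``centroids``, if given, is indexed by huc12_id with columns x, y.
    HUC-12s whose longest FCN lacks a habitat summary are dropped with a
    logged count (should not happen when summaries cover every FCN).
    """
    sum_h = {s.fcn_id: s for s in summaries_hist}
    sum_c = {s.fcn_id: s for s in summaries_curr}
    long_h = longest_fcn_per_huc12(fcns_hist, net)
    long_c = longest_fcn_per_huc12(fcns_curr, net)
    eco = net.frame.groupby("huc12_id")["ecoregion_id"].agg(lambda s: s.mode().iloc[0])

    rows = []
    dropped = 0
    for h in sorted(long_h):
        fh, fc = long_h[h], long_c.get(h)
        if fc is None or fh not in sum_h or fc not in sum_c:
            dropped += 1
            continue
        row: dict = {
            "huc12_id": h,
            "ecoregion_id": eco[h],
            "longest_hist_fcn": fh,
            "longest_curr_fcn": fc,
        }
        row.update(habitat_change_predictors(sum_h[fh], sum_c[fc]))
        row.update(length_weighted_condition(net, h))
        row.update(outlet_upstream_metrics(net, h))
        if centroids is not None:
            row["x"] = float(centroids.loc[h, "x"])
            row["y"] = float(centroids.loc[h, "y"])
        rows.append(row)
    if dropped:
        logger.info("dropped %d HUC-12s lacking a linked historical/current FCN pair", dropped)
    return pd.DataFrame(rows).set_index("huc12_id")


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a HUC-12 table usable as model predictors."""
    skip = {"ecoregion_id", "longest_hist_fcn", "longest_curr_fcn", "x", "y",
            "tbi", "tbi_p", "tbi_significant"}
    return [c for c in table.columns if c not in skip]
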