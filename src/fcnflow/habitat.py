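"""Physical habitat classification and per-FCN habitat diversity metrics.

Each stream reach is assigned one composite habitat class built from the
enabled dimensions — stream size (drainage-area thresholds), thermal regime
(August temperature thresholds), and pass-through categorical attributes
(gradient, flow regime, valley confinement) — plus a standalone waterbody
class where applicable (ocean/estuary, natural lake, artificial lake).

Per patch (FCN) we then compute:

* ``class_lengths`` — total stream km per habitat class;
* ``presence`` — classes with at least ``min_presence_km`` of stream (default
  1 km, boundary inclusive); waterbody classes need only be present;
* ``richness`` — number of classes present;
* ``rwr`` — rarity-weighted richness, Σ_h 1/n_h over present classes where
  n_h is the number of FCNs (same scenario × ecoregion) containing class h;
* ``rwr_z`` — z-score of rwr within ecoregion × scenario, making the two
  periods comparable despite differing patch counts.

The classification thresholds shipped as defaults are an editable, documented
table; substitute your own schema to match any regional classification.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delineation import FCN
from .errors import MissingAttributeError
from .network import RiverNetwork

logger = logging.getLogger(__name__)

#: Sentinel composite class for reaches with a missing categorical attribute.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HabitatSchema:
    """Rules mapping reach attributes to habitat classes.

    ``size_class_breaks`` and ``temp_class_breaks`` are strictly increasing
    upper bounds; a value falls in the first bin whose bound exceeds it, and
    beyond the last bound it takes the final label (so labels are one longer
    than breaks). Set ``temp_class_labels=()`` to disable the thermal
    dimension entirely.
    """

    size_class_breaks: Sequence[float] = (25.0, 100.0, 518.0, 2590.0, 10000.0)
    size_class_labels: Sequence[str] = (
        "headwater",
        "creek",
        "small_river",
        "medium_river",
        "large_river",
        "great_river",
    )
    temp_class_breaks: Sequence[float] = (16.0, 21.0)
    temp_class_labels: Sequence[str] = ("cold", "cool", "warm")
    pass_through_dimensions: Sequence[str] = (
        "gradient_class",
        "flow_class",
        "confinement_class",
    )
    waterbody_classes: Sequence[str] = ("ocean_estuary", "natural_lake", "artificial_lake")
    min_presence_km: float = 1.0
    count_waterbodies_in_richness: bool = True
    temp_fallback_label: str | None = None

    def __post_init__(self):
        for breaks, labels, name in (
            (self.size_class_breaks, self.size_class_labels, "size"),
            (self.temp_class_breaks, self.temp_class_labels, "temp"),
        ):
            if labels and len(labels) != len(breaks) + 1:
                raise ValueError(f"{name}: need len(labels) == len(breaks) + 1")
            if list(breaks) != sorted(set(breaks)):
                raise ValueError(f"{name}: breaks must be strictly increasing")
            if labels and len(set(labels)) != len(labels):
                raise ValueError(f"{name}: labels must be unique")


DEFAULT_SCHEMA = HabitatSchema()


@dataclass(frozen=True)
class FCNHabitatSummary:
    """Habitat composition of one FCN (see module docstring for fields)."""

    fcn_id: str
    scenario: str
    ecoregion_id: str
    class_lengths: Mapping[str, float]
    presence: frozenset
    richness: int
    rwr: float = float("nan")
    rwr_z: float = float("nan")

    @property
    def total_length_km(self) -> float:
        return float(sum(self.class_lengths.values()))


# ---------------------------------------------------------------------- #
def _bin_label(value: float, breaks: Sequence[float], labels: Sequence[str]) -> str:
    return labels[bisect_right(list(breaks), value)]


def classify_reaches(net: RiverNetwork, schema: HabitatSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Assign each reach a composite habitat class and an optional waterbody class.

    Classification is pure row-wise lookup: the class of a reach depends only
    on its own attributes, never on network context. Reaches with a missing
    categorical attribute get the ``unclassified`` sentinel (logged count);
    a missing temperature raises unless the schema provides a fallback label.
    """
    df = net.frame
    n = len(df)
    parts: list[np.ndarray] = []

    if schema.size_class_labels:
        area = df["drainage_area_km2"].to_numpy(dtype=float)
        parts.append(
            np.array([_bin_label(a, schema.size_class_breaks, schema.size_class_labels) for a in area])
        )
    if schema.temp_class_labels:
        temp = df["aug_temp_c"].to_numpy(dtype=float)
        missing = ~np.isfinite(temp)
        if missing.any() and schema.temp_fallback_label is None:
            raise MissingAttributeError(
                f"aug_temp_c missing for {int(missing.sum())} reaches and no "
                "temp_fallback_label configured"
            )
        labels = np.array(
            [
                schema.temp_fallback_label
                if not np.isfinite(t)
                else _bin_label(t, schema.temp_class_breaks, schema.temp_class_labels)
                for t in temp
            ]
        )
        parts.append(labels)
    n_sentinel = 0
    for dim in schema.pass_through_dimensions:
        col = df[dim].astype(object).to_numpy()
        vals = np.array([UNCLASSIFIED if (v is None or v != v) else str(v) for v in col])
        n_sentinel += int((vals == UNCLASSIFIED).sum())
        parts.append(vals)
    if n_sentinel:
        logger.info("%d reach attribute values missing; sentinel class used", n_sentinel)

    if parts:
        composite = np.array(["|".join(t) for t in zip(*parts)])
    else:
        composite = np.full(n, UNCLASSIFIED, dtype=object)

    wb = df["waterbody_type"].to_numpy(dtype=object)
    waterbody = np.where(np.isin(wb, list(schema.waterbody_classes)), wb, None)
    return pd.DataFrame(
        {"habitat_class": composite, "waterbody_class": waterbody}, index=df.index
    )


def habitat_presence(
    fcn: FCN, classes: pd.DataFrame, net: RiverNetwork, schema: HabitatSchema = DEFAULT_SCHEMA
) -> FCNHabitatSummary:
    """Sum class lengths over an FCN's reaches and apply the presence rule.

    A stream class is present when its total length is at least
    ``schema.min_presence_km`` (inclusive); a waterbody class is present as
    soon as any member reach carries it.
    """
    members = sorted(fcn.reach_ids)
    lengths = net.frame["length_km"].loc[members]
    cls = classes["habitat_class"].loc[members]
    class_lengths = lengths.groupby(cls).sum().to_dict()

    present = {c for c, km in class_lengths.items() if km >= schema.min_presence_km}
    wb = classes["waterbody_class"].loc[members]
    wb_present = {w for w in wb if w is not None}
    presence = frozenset(present | wb_present)
    richness = len(presence) if schema.count_waterbodies_in_richness else len(present)
    return FCNHabitatSummary(
        fcn_id=fcn.fcn_id,
        scenario=fcn.scenario,
        ecoregion_id=fcn.ecoregion_id,
        class_lengths=class_lengths,
        presence=presence,
        richness=richness,
    )


def summarize_habitat(
    fcns: Sequence[FCN], classes: pd.DataFrame, net: RiverNetwork,
    schema: HabitatSchema = DEFAULT_SCHEMA,
) -> list[FCNHabitatSummary]:
    """Per-FCN habitat summaries with rarity-weighted richness and z-scores.

    RWR is computed within each scenario × ecoregion group; z-scores within
    the same grouping (sample standard deviation, n−1).
    """
    summaries = [habitat_presence(f, classes, net, schema) for f in fcns]
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(summaries):
        groups.setdefault((s.scenario, s.ecoregion_id), []).append(i)
    out = list(summaries)
    for idx in groups.values():
        updated = rarity_weighted_richness([summaries[i] for i in idx])
        rwr = np.array([u.rwr for u in updated])
        z = zscore_by_group(rwr, np.zeros(len(rwr)))
        for j, i in enumerate(idx):
            out[i] = replace(updated[j], rwr_z=float(z[j]))
    return out


def rarity_weighted_richness(summaries: Sequence[FCNHabitatSummary]) -> list[FCNHabitatSummary]:
    """Attach rwr = Σ_{h present} 1/n_h within one scenario × ecoregion group.

    n_h is the number of FCNs in the group whose presence set contains h, so
    summing rwr across the group recovers the number of distinct classes
    present anywhere in it (each class contributes n_h × 1/n_h = 1).
    """
    if not summaries:
        return []
    counts: dict[str, int] = {}
    for s in summaries:
        for h in s.presence:
            counts[h] = counts.get(h, 0) + 1
    return [
        replace(s, rwr=float(sum(1.0 / counts[h] for h in s.presence)))
        for s in summaries
    ]


def zscore_by_group(values, groups) -> np.ndarray:
    """Z-scores within groups using the sample (n−1) standard deviation.

    A group with zero spread (or a single member) gets z = 0 with a warning
    rather than NaN, so downstream change scores stay defined.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    z = np.zeros_like(values)
    for g in pd.unique(groups):
        m = groups == g
        vals = values[m]
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"group {g!r} has zero spread; z-scores set to 0", stacklevel=2)
            z[m] = 0.0
        else:
            z[m] = (vals - vals.mean()) / sd
    return z


def habitat_table(summaries: Sequence[FCNHabitatSummary]) -> pd.DataFrame:
    """Wide-format per-FCN habitat summary (one `<class>_km` column per class)."""
    all_classes = sorted({c for s in summaries for c in s.class_lengths})
    rows = []
    for s in summaries:
        row = {
            "fcn_id": s.fcn_id,
            "scenario": s.scenario,
            "ecoregion_id": s.ecoregion_id,
            "richness": s.richness,
            "rwr": s.rwr,
            "rwr_z": s.rwr_z,
            "total_length_km": s.total_length_km,
        }
        for c in all_classes:
            row[f"{sanitize_class(c)}_km"] = s.class_lengths.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def sanitize_class(label: str) -> str:
    """Habitat-class label → safe column-name fragment."""
    return label.replace("|", ".").replace(" ", "_")
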