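"""Barrier scenarios and functionally connected network (FCN) delineation.

An FCN is a maximal habitat patch: the set of reaches mutually reachable
without crossing a passage barrier or a network terminus. A barrier sitting
on reach *r* severs the edge between *r* and its downstream neighbour, with
*r* itself kept in the upstream patch. Two standard scenarios are used:

* ``historical`` — natural fragmentation only: waterfalls that are complete
  barriers to fish passage.
* ``current`` — waterfalls plus dams of any passability class (complete,
  partial, or unknown).

Barriers flagged as removed, off the routed network, or with anadromous fish
observed upstream are excluded from both scenarios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidCategoryError, UndefinedChangeError, UnknownBarrierReachError
from .network import RiverNetwork

logger = logging.getLogger(__name__)

BARRIER_TYPES = ("waterfall", "dam")
PASSABILITY = ("complete", "partial", "unknown")
EXCLUSION_FLAGS = ("removed", "off_network", "anadromous_upstream")


@dataclass(frozen=True)
class Barrier:
    """A natural or artificial fish-passage barrier located on one reach."""

    barrier_id: str
    reach_id: str
    barrier_type: str
    passability: str = "complete"
    removed: bool = False
    off_network: bool = False
    anadromous_upstream: bool = False

    def __post_init__(self):
        if self.barrier_type not in BARRIER_TYPES:
            raise InvalidCategoryError(f"unknown barrier_type {self.barrier_type!r}")
        if self.passability not in PASSABILITY:
            raise InvalidCategoryError(f"unknown passability {self.passability!r}")


@dataclass(frozen=True)
class Scenario:
    """Selects the subset of barriers active in one period."""

    name: str
    include_types: frozenset = frozenset()
    exclusion_flags: frozenset = frozenset(EXCLUSION_FLAGS)


#: Waterfalls only (and only those that are complete barriers).
HISTORICAL = Scenario("historical", frozenset({"waterfall"}))
#: Waterfalls plus dams of every passability class.
CURRENT = Scenario("current", frozenset({"waterfall", "dam"}))

SCENARIOS = {"historical": HISTORICAL, "current": CURRENT}


@dataclass(frozen=True)
class FCN:
    """One functionally connected network (habitat patch)."""

    fcn_id: str
    scenario: str
    reach_ids: frozenset
    total_length_km: float
    ecoregion_id: str


# ---------------------------------------------------------------------- #
def load_barrier_table(source) -> list[Barrier]:
    """Read a barrier CSV (booleans encoded as 0/1)."""
    df = pd.read_csv(source, dtype={"barrier_id": str, "reach_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Barrier(
                barrier_id=row.barrier_id,
                reach_id=row.reach_id,
                barrier_type=row.barrier_type,
                passability=getattr(row, "passability", "complete"),
                removed=bool(getattr(row, "removed", 0)),
                off_network=bool(getattr(row, "off_network", 0)),
                anadromous_upstream=bool(getattr(row, "anadromous_upstream", 0)),
            )
        )
    return out


def write_barrier_table(barriers, path) -> None:
    rows = [
        {
            "barrier_id": b.barrier_id,
            "reach_id": b.reach_id,
            "barrier_type": b.barrier_type,
            "passability": b.passability,
            "removed": int(b.removed),
            "off_network": int(b.off_network),
            "anadromous_upstream": int(b.anadromous_upstream),
        }
        for b in barriers
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def select_barriers(barriers, scenario: Scenario) -> list[Barrier]:
    """Barriers active under ``scenario``.

    Waterfalls count only when they are complete barriers (natural-barrier
    inventories are restricted to falls impassable to fish); dams count in
    whatever passability class they carry. Any set exclusion flag
    disqualifies a barrier. An empty result is valid.
    """
    out = []
    for b in barriers:
        if b.barrier_type not in scenario.include_types:
            continue
        if any(getattr(b, flag) for flag in scenario.exclusion_flags):
            continue
        if b.barrier_type == "waterfall" and b.passability != "complete":
            continue
        out.append(b)
    return out


def delineate_fcns(
    net: RiverNetwork, active_barriers, scenario_name: str = "current"
) -> list[FCN]:
    """Partition the network into FCNs given the active barrier set.

    Equivalent to deleting, for every barrier on reach *r*, the undirected
    edge *r*–downstream(*r*) and taking connected components; computed with a
    union-find over the reach forest, so the result is independent of reach
    iteration order. A barrier on a terminus reach has no edge to cut and is
    a logged no-op; multiple barriers on one reach collapse to a single cut.
    """
    ids = net.reach_ids
    index = {rid: i for i, rid in enumerate(ids)}
    cut: set[str] = set()
    for b in active_barriers:
        if b.reach_id not in index:
            raise UnknownBarrierReachError(
                f"barrier {b.barrier_id!r} sits on unknown reach {b.reach_id!r}"
            )
        if net.downstream[b.reach_id] is None:
            logger.info(
                "barrier %s on terminus reach %s cuts nothing", b.barrier_id, b.reach_id
            )
        cut.add(b.reach_id)

    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for rid in ids:
        did = net.downstream[rid]
        if did is None or rid in cut:
            continue
        ri, di = find(index[rid]), find(index[did])
        if ri != di:
            parent[ri] = di

    groups: dict[int, list[str]] = {}
    for rid in ids:
        groups.setdefault(find(index[rid]), []).append(rid)

    lengths = net.frame["length_km"]
    ecoregions = net.frame["ecoregion_id"]
    fcns = []
    for members in groups.values():
        members = sorted(members)
        total = float(lengths.loc[members].sum())
        eco = _dominant_ecoregion(members, lengths, ecoregions)
        fcns.append(
            FCN(
                fcn_id=members[0],
                scenario=scenario_name,
                reach_ids=frozenset(members),
                total_length_km=total,
                ecoregion_id=eco,
            )
        )
    fcns.sort(key=lambda f: f.fcn_id)
    return fcns


def _dominant_ecoregion(members, lengths, ecoregions) -> str:
    eco = ecoregions.loc[members]
    uniq = eco.unique()
    if len(uniq) == 1:
        return str(uniq[0])
    # drainage-defined ecoregions should not split an FCN; pick by stream km
    by_len = lengths.loc[members].groupby(eco).sum().sort_values(ascending=False)
    logger.warning("FCN spans %d ecoregions; assigning %s by length", len(uniq), by_len.index[0])
    return str(by_len.index[0])


def summarize_fcns(fcns, by: str = "ecoregion_id") -> pd.DataFrame:
    """Count and mean total length of FCNs per ecoregion, plus an all-groups row."""
    if not fcns:
        return pd.DataFrame(columns=[by, "fcn_count", "mean_length_km", "total_length_km"])
    df = pd.DataFrame(
        {
            by: [f.ecoregion_id for f in fcns],
            "total_length_km": [f.total_length_km for f in fcns],
        }
    )
    g = df.groupby(by)["total_length_km"].agg(fcn_count="size", mean_length_km="mean",
                                              total_length_km="sum").reset_index()
    overall = pd.DataFrame(
        {
            by: ["all"],
            "fcn_count": [len(df)],
            "mean_length_km": [df["total_length_km"].mean()],
            "total_length_km": [df["total_length_km"].sum()],
        }
    )
    return pd.concat([g, overall], ignore_index=True)


# ---------------------------------------------------------------------- #
def percent_change(historical: float, current: float) -> float:
    """100 × (current − historical) / historical.

    Negative values indicate loss relative to the historical baseline.
    Undefined (raises) when the historical value is zero.
    """
    if historical == 0:
        raise UndefinedChangeError("percent change from a zero historical value is undefined")
    return 100.0 * (current - historical) / historical


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (reporting convention)."""
    if not math.isfinite(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def membership_frame(fcns) -> pd.DataFrame:
    """Long-format reach → FCN assignment table."""
    rows = []
    for f in fcns:
        for rid in sorted(f.reach_ids):
            rows.append({"reach_id": rid, "fcn_id": f.fcn_id, "scenario": f.scenario})
    return pd.DataFrame(rows)
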