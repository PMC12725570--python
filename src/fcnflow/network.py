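"""Dendritic stream-reach networks: data model, I/O, validation, traversal.

The unit of analysis is the confluence-to-confluence stream reach. Each reach
points to at most one downstream neighbour, so a drainage is an in-tree rooted
at its terminus (ocean, estuary, or hydrological disconnect) and a reach table
may describe a forest of independent drainages. Confluences are implicit: two
or more reaches sharing the same downstream neighbour.

Reach tables are plain CSV (or Parquet) files with one row per reach. An empty
or null ``downstream_id`` marks a network terminus.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CycleError,
    DanglingDownstreamError,
    DuplicateReachIdError,
    EmptyNetworkError,
    InvalidCategoryError,
    NonPositiveValueError,
    UnknownReachError,
)

logger = logging.getLogger(__name__)

#: Waterbody categories a reach may carry. ``none`` means an ordinary stream
#: reach; the other three are standalone habitat classes downstream.
WATERBODY_TYPES = ("none", "ocean_estuary", "natural_lake", "artificial_lake")

#: Columns every reach table must provide.
REQUIRED_COLUMNS = (
    "reach_id",
    "downstream_id",
    "length_km",
    "drainage_area_km2",
    "ecoregion_id",
    "huc12_id",
)

#: Optional attribute columns; absent ones are filled with NaN / defaults.
OPTIONAL_COLUMNS = (
    "aug_temp_c",
    "gradient_class",
    "flow_class",
    "confinement_class",
    "waterbody_type",
    "hwi",
    "local_hydro_reg",
    "upstream_dam_density",
    "upstream_dam_storage",
)

_ID_COLUMNS = ("reach_id", "downstream_id", "ecoregion_id", "huc12_id")

#: Default drainage-area cutoff (km²) below which reaches are dropped to
#: control for variable drainage density in the source hydrography.
MIN_DRAINAGE_AREA_KM2 = 2.5


class RiverNetwork:
    """A validated forest of dendritic reach trees.

    Parameters
    ----------
    reaches : pandas.DataFrame
        One row per reach, indexed by ``reach_id`` (string), with a
        ``downstream_id`` column holding a reach_id or ``None``.
    validate : bool
        Run structural validation (cycles, dangling pointers, positive
        lengths/areas). Drainage-area monotonicity violations are logged as
        warnings, never raised: real hydrography contains divergences.
    """

    def __init__(self, reaches: pd.DataFrame, validate: bool = True):
        df = reaches.copy()
        if df.index.name != "reach_id":
            if "reach_id" not in df.columns:
                raise DuplicateReachIdError("reach table lacks a reach_id column")
            df = df.set_index("reach_id", drop=True)
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateReachIdError(f"duplicate reach_id values: {dupes[:5]}")
        down = df["downstream_id"]
        down = down.where(down.notna(), None)
        df["downstream_id"] = [None if d is None or d == "" else str(d) for d in down]
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = "none" if col == "waterbody_type" else np.nan
        df["waterbody_type"] = df["waterbody_type"].fillna("none")
        self._df = df
        self._downstream: dict[str, str | None] = dict(df["downstream_id"])
        self._children: dict[str, list[str]] = {rid: [] for rid in df.index}
        for rid, did in self._downstream.items():
            if did is not None and did in self._children:
                self._children[did].append(rid)
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            raise EmptyNetworkError("network has no reaches")
        for col in ("length_km", "drainage_area_km2"):
            bad = df.index[~(df[col].to_numpy(dtype=float) > 0)]
            if len(bad):
                raise NonPositiveValueError(
                    f"{col} must be positive; offending reaches: {list(bad[:5])}"
                )
        bad_wb = set(df["waterbody_type"]) - set(WATERBODY_TYPES)
        if bad_wb:
            raise InvalidCategoryError(f"unknown waterbody_type values: {sorted(bad_wb)}")
        ids = set(df.index)
        dangling = [
            rid for rid, did in self._downstream.items() if did is not None and did not in ids
        ]
        if dangling:
            raise DanglingDownstreamError(
                f"downstream_id not found for reaches: {dangling[:5]}"
            )
        self._check_acyclic()
        self._check_monotone_area()

    def _check_acyclic(self) -> None:
        # colour walk: 0 unseen, 1 on current path, 2 cleared
        colour: dict[str, int] = {}
        for start in self._downstream:
            if colour.get(start):
                continue
            path = []
            node: str | None = start
            while node is not None and not colour.get(node):
                colour[node] = 1
                path.append(node)
                node = self._downstream[node]
            if node is not None and colour[node] == 1:
                raise CycleError(f"cycle detected through reach {node!r}")
            for n in path:
                colour[n] = 2

    def _check_monotone_area(self) -> None:
        area = self._df["drainage_area_km2"]
        n_bad = 0
        for rid, did in self._downstream.items():
            if did is not None and area[did] < area[rid] - 1e-9:
                n_bad += 1
        if n_bad:
            logger.warning(
                "drainage area decreases downstream across %d reach pairs "
                "(kept; flagged for provenance)",
                n_bad,
            )

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, reach_id: str) -> bool:
        return reach_id in self._downstream

    @property
    def reach_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def terminus_ids(self) -> set[str]:
        return {rid for rid, did in self._downstream.items() if did is None}

    @property
    def downstream(self) -> Mapping[str, str | None]:
        return self._downstream

    @property
    def children(self) -> Mapping[str, list[str]]:
        """Immediate upstream neighbours of each reach."""
        return self._children

    def to_frame(self) -> pd.DataFrame:
        """Copy of the reach table (indexed by reach_id)."""
        return self._df.copy()

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying reach table; treat as read-only."""
        return self._df

    # ------------------------------------------------------------------ #
    def upstream_set(self, reach_id: str) -> set[str]:
        """All reaches whose downstream path passes through ``reach_id``.

        Inclusive of ``reach_id`` itself (the reflexive-transitive closure of
        the upstream relation).
        """
        if reach_id not in self._downstream:
            raise UnknownReachError(f"reach {reach_id!r} not in network")
        out: set[str] = set()
        stack = [reach_id]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self._children[node])
        return out

    def subset(self, keep_ids: Iterable[str]) -> "RiverNetwork":
        """Restrict to ``keep_ids``; severed downstream pointers become termini."""
        keep = set(keep_ids)
        if not keep:
            raise EmptyNetworkError("subset would leave an empty network")
        df = self._df.loc[self._df.index.isin(keep)].copy()
        severed = [
            rid
            for rid in df.index
            if df.at[rid, "downstream_id"] is not None
            and df.at[rid, "downstream_id"] not in keep
        ]
        if severed:
            logger.info("subset severed %d downstream pointers (new termini)", len(severed))
            for rid in severed:
                df.at[rid, "downstream_id"] = None
        return RiverNetwork(df)


# ---------------------------------------------------------------------- #
def load_reach_table(source) -> RiverNetwork:
    """Read a reach table from CSV or Parquet and validate it.

    Row order never affects the result. Columns beyond the documented set are
    ignored with a logged notice. An empty string or null ``downstream_id``
    denotes a network terminus.
    """
    path = str(source)
    if path.endswith((".parquet", ".pq")):
        df = pd.read_parquet(path)
        df["reach_id"] = df["reach_id"].astype(str)
    else:
        df = pd.read_csv(path, dtype={c: str for c in _ID_COLUMNS})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reach table missing required columns: {missing}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extras = [c for c in df.columns if c not in known]
    if extras:
        logger.info("ignoring %d extra reach-table columns: %s", len(extras), extras)
        df = df.drop(columns=extras)
    return RiverNetwork(df)


def write_reach_table(net: RiverNetwork, path) -> None:
    """Write the reach table so that :func:`load_reach_table` round-trips."""
    df = net.to_frame().reset_index()
    df["downstream_id"] = df["downstream_id"].map(lambda d: "" if d is None else d)
    path = str(path)
    if path.endswith((".parquet", ".pq")):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def filter_small_reaches(
    net: RiverNetwork, min_area_km2: float = MIN_DRAINAGE_AREA_KM2
) -> RiverNetwork:
    """Drop reaches with drainage area below ``min_area_km2``.

    Because drainage area is (nominally) non-decreasing downstream, the
    removed set is upstream-closed and the remainder is itself a valid
    network; any pointer severed by a monotonicity violation in the input
    becomes a terminus, logged by :meth:`RiverNetwork.subset`.
    """
    area = net.frame["drainage_area_km2"].to_numpy(dtype=float)
    keep = [rid for rid, a in zip(net.reach_ids, area) if a >= min_area_km2]
    if not keep:
        raise EmptyNetworkError(
            f"no reach has drainage area >= {min_area_km2} km2; refusing to empty the network"
        )
    return net.subset(keep)


def upstream_set(net: RiverNetwork, reach_id: str) -> set[str]:
    """Module-level alias for :meth:`RiverNetwork.upstream_set`."""
    return net.upstream_set(reach_id)
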