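"""End-to-end pipeline: validate → delineate → habitat → link → TBI → RF.

A single flat YAML config drives the run; every stage writes its outputs
before the next starts, all randomness flows from the config seeds, and a
rerun with the same config is bit-identical for the deterministic stages.
The run report is a JSON document validated against the pydantic contract
in :mod:`fcnflow.report` (its JSON schema ships with the package).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import report as report_mod
from .delineation import (
    SCENARIOS,
    delineate_fcns,
    load_barrier_table,
    membership_frame,
    percent_change,
    select_barriers,
    summarize_fcns,
)
from .errors import FcnflowError
from .habitat import DEFAULT_SCHEMA, HabitatSchema, classify_reaches, habitat_table, summarize_habitat
from .linkage import build_huc12_table, predictor_columns
from .network import filter_small_reaches, load_reach_table
from .spatial import SpatialRandomForest, prune_predictors
from .tbi import CommunityPair, dominance_test, species_paired_tests, tbi_permutation_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key-value run configuration (see ``RunConfig.from_yaml``)."""

    reaches: str
    barriers: str
    community_historical: str
    community_current: str
    centroids: str | None = None
    species_meta: str | None = None  # CSV: species_id, range_type
    out_dir: str = "fcnflow_out"
    min_area_km2: float = 2.5
    tbi_n_perm: int = 9999
    tbi_alpha: float = 0.05
    tbi_correction: str = "holm"
    tbi_seed: int = 0
    rf_enabled: bool = True
    rf_runs: int = 30
    rf_seed: int = 0
    rf_thresholds: list | None = None
    rf_min_sites: int = 30
    log_level: str = "INFO"
    schema: HabitatSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        schema = raw.pop("schema", None)
        cfg = cls(**raw)
        if schema:
            cfg.schema = HabitatSchema(**schema)
        return cfg


def _require(path: str | None, stage: str) -> str:
    if path is None or not Path(path).exists():
        raise FcnflowError(f"stage {stage!r}: input file not found: {path!r}")
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(cfg).items() if k != "schema"}}

    # -- validate ----------------------------------------------------- #
    net = load_reach_table(_require(cfg.reaches, "validate"))
    net = filter_small_reaches(net, cfg.min_area_km2)
    report["validate"] = {
        "n_reaches": len(net),
        "n_termini": len(net.terminus_ids),
        "total_length_km": float(net.frame["length_km"].sum()),
    }

    # -- delineate ---------------------------------------------------- #
    barriers = load_barrier_table(_require(cfg.barriers, "delineate"))
    fcns, summaries_by_scenario = {}, {}
    for name, scenario in SCENARIOS.items():
        active = select_barriers(barriers, scenario)
        off_net = [b for b in active if b.reach_id not in net]
        if off_net:
            logger.info(
                "%s scenario: %d barriers sit on reaches excluded by the "
                "drainage-area filter; ignored", name, len(off_net),
            )
            active = [b for b in active if b.reach_id in net]
        fcns[name] = delineate_fcns(net, active, name)
        membership_frame(fcns[name]).to_csv(out / f"fcn_membership_{name}.csv", index=False)
        summ = summarize_fcns(fcns[name])
        summ.to_csv(out / f"fcn_summary_{name}.csv", index=False)
        summaries_by_scenario[name] = summ
    h = summaries_by_scenario["historical"]
    c = summaries_by_scenario["current"]
    h_all = h[h["ecoregion_id"] == "all"].iloc[0]
    c_all = c[c["ecoregion_id"] == "all"].iloc[0]
    report["delineate"] = {
        "historical_fcn_count": int(h_all["fcn_count"]),
        "current_fcn_count": int(c_all["fcn_count"]),
        "fcn_count_pct_change": percent_change(h_all["fcn_count"], c_all["fcn_count"]),
        "historical_mean_length_km": float(h_all["mean_length_km"]),
        "current_mean_length_km": float(c_all["mean_length_km"]),
        "mean_length_pct_change": percent_change(
            h_all["mean_length_km"], c_all["mean_length_km"]
        ),
    }

    # -- habitat ------------------------------------------------------ #
    import dataclasses

    with open(out / "habitat_schema.json", "w") as fh:  # provenance export
        json.dump(dataclasses.asdict(cfg.schema), fh, indent=2, default=list)
    classes = classify_reaches(net, cfg.schema)
    hab = {
        name: summarize_habitat(fcns[name], classes, net, cfg.schema)
        for name in fcns
    }
    for name, summ in hab.items():
        habitat_table(summ).to_csv(out / f"habitat_{name}.csv", index=False)
    report["habitat"] = {
        "n_classes": int(classes["habitat_class"].nunique()),
        "mean_richness_historical": float(np.mean([s.richness for s in hab["historical"]])),
        "mean_richness_current": float(np.mean([s.richness for s in hab["current"]])),
    }

    # -- link --------------------------------------------------------- #
    centroids = (
        pd.read_csv(cfg.centroids, index_col="huc12_id") if cfg.centroids else None
    )
    huc = build_huc12_table(
        net, fcns["historical"], fcns["current"], hab["historical"], hab["current"], centroids
    )
    huc.to_csv(out / "huc12_predictors.csv")
    report["link"] = {
        "n_huc12": int(len(huc)),
        "mean_length_km_pctchg": float(huc["length_km_pctchg"].mean()),
    }

    # -- tbi ---------------------------------------------------------- #
    pair = CommunityPair.from_csv(
        _require(cfg.community_historical, "tbi"), _require(cfg.community_current, "tbi")
    )
    tbi = tbi_permutation_test(
        pair, n_perm=cfg.tbi_n_perm, seed=cfg.tbi_seed, alpha=cfg.tbi_alpha
    )
    tbi.to_csv(out / "tbi_results.csv")
    dom = dominance_test(tbi, n_perm=cfg.tbi_n_perm, seed=cfg.tbi_seed, alpha=cfg.tbi_alpha)
    with open(out / "dominance.json", "w") as fh:
        json.dump(dom, fh, indent=2)
    range_types = None
    if cfg.species_meta:
        meta = pd.read_csv(cfg.species_meta, dtype=str)
        range_types = dict(zip(meta["species_id"], meta["range_type"]))
    species = species_paired_tests(
        pair, n_perm=cfg.tbi_n_perm, seed=cfg.tbi_seed, correction=cfg.tbi_correction,
        alpha=cfg.tbi_alpha, range_types=range_types,
    )
    species.to_csv(out / "species_change.csv")
    report["tbi"] = {
        "mean_D": float(np.nanmean(tbi["D"])),
        "mean_B": dom["mean_B"],
        "mean_C": dom["mean_C"],
        "dominance_direction": dom["direction"],
        "dominance_p": dom["p"],
        "n_significant_sites": int(tbi["significant"].sum()),
        "n_sites": int(len(tbi)),
        "n_significant_species": int(species["significant"].sum()),
    }

    # -- rf ----------------------------------------------------------- #
    if cfg.rf_enabled:
        rf_block = _run_rf_stage(cfg, huc, tbi, out)
        report["rf"] = rf_block

    return write_report(report, out / "report.json")


def _run_rf_stage(cfg: RunConfig, huc: pd.DataFrame, tbi: pd.DataFrame, out: Path) -> dict:
    merged = huc.join(tbi[["D"]], how="inner").dropna(subset=["D"])
    Xcols = predictor_columns(huc)
    X = merged[Xcols].copy()
    # percent changes undefined from a zero historical baseline carry their
    # signal in the presence-change column; the pct column is centred to 0
    X = X.fillna(0.0)
    y = merged["D"].to_numpy()
    kept, removal_log = prune_predictors(X, y)
    removal_log.to_csv(out / "rf_removed_predictors.csv", index=False)
    coords = merged[["x", "y"]].to_numpy()
    model = SpatialRandomForest(
        y, X[kept], coords, thresholds=cfg.rf_thresholds, min_sites=cfg.rf_min_sites
    )
    res = model.fit(n_runs=cfg.rf_runs, seed=cfg.rf_seed)
    res.importances.assign(run=range(res.n_runs)).melt(
        id_vars="run", var_name="predictor", value_name="importance"
    ).to_csv(out / "rf_importance.csv", index=False)
    pd.DataFrame(
        [
            {"threshold": m.threshold, "I": m.I, "expected_I": m.expected_I, "p": m.p_value}
            for m in res.residual_moran
        ]
    ).to_csv(out / "rf_residual_moran.csv", index=False)
    med = float(np.median(res.oob_r2))
    return {
        "n_sites": int(len(y)),
        "predictors_kept": kept,
        "spatial_predictors_used": res.spatial_predictors_used,
        "oob_r2_median": med,
        "oob_r2_mad": float(np.median(np.abs(res.oob_r2 - med))),
        "top_predictors": list(res.median_importance().head(5).index),
    }


def write_report(report: dict, path) -> Path:
    """Validate the report against the shipped contract and write it."""
    validated = report_mod.RunReport.model_validate(report)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(validated.model_dump_json(indent=2))
    return path.parent
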