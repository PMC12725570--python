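"""Run-report contract.

The pipeline report is validated against these pydantic models before being
written; ``report_schema.json`` (shipped alongside this module) is the JSON
schema generated from :class:`RunReport`, published so external tooling can
validate reports without importing the package.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict


class ValidateBlock(BaseModel):
    n_reaches: int
    n_termini: int
    total_length_km: float


class DelineateBlock(BaseModel):
    historical_fcn_count: int
    current_fcn_count: int
    fcn_count_pct_change: float
    historical_mean_length_km: float
    current_mean_length_km: float
    mean_length_pct_change: float


class HabitatBlock(BaseModel):
    n_classes: int
    mean_richness_historical: float
    mean_richness_current: float


class LinkBlock(BaseModel):
    n_huc12: int
    mean_length_km_pctchg: float


class TbiBlock(BaseModel):
    mean_D: float
    mean_B: float
    mean_C: float
    dominance_direction: str
    dominance_p: float
    n_significant_sites: int
    n_sites: int
    n_significant_species: int


class RfBlock(BaseModel):
    n_sites: int
    predictors_kept: list[str]
    spatial_predictors_used: list[str]
    oob_r2_median: float
    oob_r2_mad: float
    top_predictors: list[str]


class RunReport(BaseModel):
    model_config = ConfigDict(extra="allow")

    config: dict
    validate_: Optional[ValidateBlock] = None
    delineate: Optional[DelineateBlock] = None
    habitat: Optional[HabitatBlock] = None
    link: Optional[LinkBlock] = None
    tbi: Optional[TbiBlock] = None
    rf: Optional[RfBlock] = None

    def __init__(self, **data):
        # accept the stage name "validate" (a pydantic-reserved word)
        if "validate" in data:
            data["validate_"] = data.pop("validate")
        super().__init__(**data)

    def model_dump_json(self, **kw) -> str:
        d = self.model_dump(exclude_none=True, **{k: v for k, v in kw.items() if k != "indent"})
        if "validate_" in d:
            d["validate"] = d.pop("validate_")
        return json.dumps(d, indent=kw.get("indent"), sort_keys=True, default=str)


def published_schema() -> dict:
    """The JSON schema shipped with the package."""
    with resources.files(__package__).joinpath("report_schema.json").open() as fh:
        return json.load(fh)
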