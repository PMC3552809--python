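"""Structured YAML configuration for CLI runs.

Example::

    grid: {first_onset_year: 1971, first_obs_year: 1991, last_year: 2006}
    pre_obs_rule: {flat_value: 0.01, flat_until: 1981, ramp_from: 1982}
    mortality_anchors: [[1971, 0.010], [1984, 0.014], [1985, 0.014],
                        [1995, 0.066], [1999, 0.015], [2006, 0.010]]
    scenario: {name: primary, cessation_rate: 0.04, mortality_offset: 0.0}
    fit: {tol: 1.0e-9, maxiter: 10000}
    bootstrap: {n_resamples: 500, assumption_sd: 0.01, level: 0.95, seed: 1}

Every block is optional; omitted blocks fall back to the defaults above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .bootstrap import BootstrapSpec
from .estimate import FitSettings, PreObsRule
from .model import YearGrid
from .rates import MortalityAnchors, Scenario, build_mortality, default_mortality_anchors

__all__ = ["AppConfig", "load_config"]


@dataclass
class AppConfig:
    grid: YearGrid
    rule: PreObsRule
    anchors: MortalityAnchors
    scenario: Scenario
    fit_settings: FitSettings
    bootstrap_spec: BootstrapSpec
    bootstrap_level: float = 0.95

    def mortality(self) -> np.ndarray:
        return build_mortality(self.grid, self.anchors)


def _default_config() -> AppConfig:
    return AppConfig(
        grid=YearGrid(1971, 1991, 2006),
        rule=PreObsRule(),
        anchors=default_mortality_anchors(),
        scenario=Scenario("primary", cessation_rate=0.04, mortality_offset=0.0, is_default=True),
        fit_settings=FitSettings(),
        bootstrap_spec=BootstrapSpec(),
    )


def load_config(path: Optional[str] = None) -> AppConfig:
    cfg = _default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "grid" in raw:
        cfg.grid = YearGrid(**raw["grid"])
    if "pre_obs_rule" in raw:
        cfg.rule = PreObsRule(**raw["pre_obs_rule"])
    if "mortality_anchors" in raw:
        cfg.anchors = MortalityAnchors(tuple(map(tuple, raw["mortality_anchors"])))
    if "scenario" in raw:
        cfg.scenario = Scenario(**raw["scenario"])
    if "fit" in raw:
        cfg.fit_settings = FitSettings(**raw["fit"])
    if "bootstrap" in raw:
        b = dict(raw["bootstrap"])
        cfg.bootstrap_level = float(b.pop("level", 0.95))
        cfg.bootstrap_spec = BootstrapSpec(**b)
    return cfg
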