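"""Run configuration: every model constant in one overridable, serialisable place.

The published analysis scatters its constants across prose (secretory
formula constants, sigmoid branch parameters, classification and
antibody thresholds); :class:`RunConfig` collects them with those values
as defaults and round-trips through a human-editable YAML file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import ANTIBODY_THRESHOLD, SEVERE_TSH_THRESHOLD, SH_TSH_THRESHOLD
from .population import LogisticBranch, PopulationCurve
from .spina import SpinaConstants

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline, defaulting to the published values."""

    constants: SpinaConstants = field(default_factory=SpinaConstants)
    curve: PopulationCurve = field(default_factory=PopulationCurve)
    sh_tsh_threshold: float = SH_TSH_THRESHOLD        # mIU/L
    severe_tsh_threshold: float = SEVERE_TSH_THRESHOLD  # mIU/L
    antibody_threshold: float = ANTIBODY_THRESHOLD    # IU/mL
    pct_decimals: int = 1     # group-level percentage rounding
    gt_sig_figs: int = 3      # human-readable GT rounding

    def __post_init__(self) -> None:
        if not 0 < self.sh_tsh_threshold < self.severe_tsh_threshold:
            raise ValueError("TSH thresholds must be positive and ordered")
        if not self.antibody_threshold > 0:
            raise ValueError("antibody threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "spina_constants": asdict(self.constants),
            "population_curve": {
                "low_ft4_branch": asdict(self.curve.low),
                "high_ft4_branch": asdict(self.curve.high),
                "branch_boundary_ft4": self.curve.boundary,
            },
            "thresholds": {
                "sh_tsh": self.sh_tsh_threshold,
                "severe_tsh": self.severe_tsh_threshold,
                "antibody": self.antibody_threshold,
            },
            "formatting": {
                "pct_decimals": self.pct_decimals,
                "gt_sig_figs": self.gt_sig_figs,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        if "spina_constants" in data:
            kwargs["constants"] = SpinaConstants(**data["spina_constants"])
        if "population_curve" in data:
            pc = data["population_curve"]
            kwargs["curve"] = PopulationCurve(
                low=LogisticBranch(**pc["low_ft4_branch"]),
                high=LogisticBranch(**pc["high_ft4_branch"]),
                boundary=pc.get("branch_boundary_ft4", 12.0),
            )
        th = data.get("thresholds", {})
        if "sh_tsh" in th:
            kwargs["sh_tsh_threshold"] = th["sh_tsh"]
        if "severe_tsh" in th:
            kwargs["severe_tsh_threshold"] = th["severe_tsh"]
        if "antibody" in th:
            kwargs["antibody_threshold"] = th["antibody"]
        fm = data.get("formatting", {})
        if "pct_decimals" in fm:
            kwargs["pct_decimals"] = fm["pct_decimals"]
        if "gt_sig_figs" in fm:
            kwargs["gt_sig_figs"] = fm["gt_sig_figs"]
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; absent keys keep their published defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
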