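"""Pipeline configuration.

All tunable rule parameters live in one dataclass so that every filter and
phase boundary used by the labeling rules is auditable and can be loaded
from a YAML file for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class LifeHistoryConfig:
    """Rule parameters for reproductive-state segmentation and filtering.

    Units are days unless noted otherwise.

    Attributes
    ----------
    gestation_mean : int
        Mean gestation length for a live birth; used to back-date a
        conception when no conception milestone is present.
    trimester_len : int
        Length of the first two trimesters; the third runs to term.
    swelling_len_range : tuple of int
        Closed interval of acceptable sexual-swelling lengths
        (follicular phase plus the five-day periovulatory window). Cycles
        outside this window are excluded as aberrant.
    periovulatory_days : int
        Length of the ovulation window ending the day before
        deturgescence of the sexual skin.
    ppa_max : int
        Maximum retained length of a postpartum-amenorrhea interval.
    postpartum_excl_days : int
        Days immediately postpartum excluded from analysis (residual
        pregnancy hormone levels).
    preresumption_days : int
        Width of the pre-resumption window (the final PPA period, which
        overrides the month-based periods).
    month_days : int
        Days per "reproductive month" (both for PPA periods and for the
        lag bins of the autocorrelation analysis).
    weaning_weeks : int
        Typical infant weaning age; PPA period 4 nominally runs from
        9 months postpartum to weaning.
    """

    gestation_mean: int = 178
    trimester_len: int = 60
    swelling_len_range: tuple[int, int] = (10, 39)
    periovulatory_days: int = 5
    ppa_max: int = 496
    postpartum_excl_days: int = 7
    preresumption_days: int = 30
    month_days: int = 30
    weaning_weeks: int = 70

    @property
    def weaning_days(self) -> int:
        return self.weaning_weeks * 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LifeHistoryConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "swelling_len_range" in raw:
            raw["swelling_len_range"] = tuple(raw["swelling_len_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["swelling_len_range"] = list(d["swelling_len_range"])
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class AnalysisConfig:
    """Parameters of the compositional / statistical layer."""

    pseudocount: float = 1.0
    prevalence_common: float = 0.20   # inclusive (>=): "common" taxa
    prevalence_floor: float = 0.05    # strict (>): analysis-set ASV floor
    effect_threshold: float = 0.4     # |CLR effect| cut for reporting
    q_threshold: float = 0.05
    max_lag_bin: int = 6
    life_history: LifeHistoryConfig = field(default_factory=LifeHistoryConfig)
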