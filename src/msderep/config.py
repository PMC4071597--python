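"""Pipeline configuration with instrument-method defaults.

Defaults mirror the acquisition and processing method the package targets:
QTOF auto-MS/MS above 50,000 counts with a 0.5 s cycle, at most three
precursors per cycle and a 0.04 min exclusion window at 10/20/40 eV;
search tolerances of 50 ppm + 2 mDa; minimum forward/reverse scores of
50/50 (with a stricter 50/70 preset); full-scan screening with an area
cutoff of 10,000 counts·min-equivalents, isotope score ≥ 70, and a feature
quality threshold of 99.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .chem import MassTolerance

__all__ = ["DDAParams", "Config", "PRESETS"]


@dataclass(frozen=True)
class DDAParams:
    """Data-dependent acquisition settings."""

    threshold: float = 50_000.0  # counts: minimum full-scan intensity
    cycle_time: float = 0.5  # s
    top_n: int = 3  # precursors per cycle
    exclusion: float = 0.04  # min: dynamic exclusion window
    energies: Tuple[float, ...] = (10.0, 20.0, 40.0)  # eV


@dataclass(frozen=True)
class Config:
    tol_precursor: MassTolerance = MassTolerance(50.0, 2.0)
    tol_product: MassTolerance = MassTolerance(50.0, 2.0)
    tol_fullscan: MassTolerance = MassTolerance(50.0, 2.0)
    min_forward: float = 50.0
    min_reverse: float = 50.0
    min_isotope_score: float = 70.0
    min_area: float = 10_000.0
    min_feature_quality: float = 99.0
    saturation_ceiling: Optional[float] = None  # counts; None disables rule (a)
    isotope_deviation_limit: float = 5.0  # %-points, saturation rule (b)
    height_fraction: float = 0.10  # merge scans below this fraction of apex
    rt_window: float = 0.05  # min: adduct/apex coherence window
    rt_match_window: float = 0.30  # min: |query RT - library RT| agreement
    dda: DDAParams = field(default_factory=DDAParams)
    max_precursors_per_run: Optional[int] = 200  # "largest peaks" cap
    check_trimers: bool = False  # 3M species in the dimer-artifact check

    def with_preset(self, name: str) -> "Config":
        try:
            return replace(self, **PRESETS[name])
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


#: Named threshold presets; "recommended" is the stricter reverse setting
#: favoured for compounds with sparse fragmentation.
PRESETS = {
    "default": {"min_forward": 50.0, "min_reverse": 50.0},
    "recommended": {"min_forward": 50.0, "min_reverse": 70.0},
}
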