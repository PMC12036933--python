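"""Study-design arithmetic: dose conversion and cell-age windows.

Interspecies dose conversion follows the body-surface-area convention:
the animal dose (mg/kg) times a species factor gives the human
equivalent dose (0.08 is the mouse factor, used here as the closest
listed body size to a zebra finch).  The birthdating window follows
from the BrdU injection schedule: cells labeled on days ``k`` before
perfusion are ``k`` days post-mitosis at perfusion.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DoseSpec",
    "BrduSchedule",
    "DesignError",
    "human_equivalent_dose",
    "dose_ratio_to_child_range",
    "brdu_age_window",
]


class DesignError(ValueError):
    """Raised for non-physical dose or schedule parameters."""


@dataclass(frozen=True)
class DoseSpec:
    """An animal dose and its human-comparison anchors.

    Defaults reproduce the study treatment: 40 mg/kg atorvastatin daily,
    mouse conversion factor 0.08, pediatric atorvastatin range
    0.5–1.0 mg/kg (10–20 mg/day at a standard 20 kg child weight).
    """

    animal_dose: float = 40.0  # mg/kg
    species_factor: float = 0.08
    child_dose_range: tuple[float, float] = (0.5, 1.0)  # mg/kg

    def __post_init__(self) -> None:
        if self.animal_dose <= 0:
            raise DesignError("animal dose must be positive")
        if not (0.0 < self.species_factor <= 1.0):
            raise DesignError("species factor must lie in (0, 1]")
        lo, hi = self.child_dose_range
        if lo <= 0 or hi <= 0:
            raise DesignError("child dose range bounds must be positive")
        if lo > hi:
            raise DesignError("child dose range must be (low, high)")


@dataclass(frozen=True)
class BrduSchedule:
    """BrdU injection days counted backwards from perfusion.

    Defaults: three injections per day on days 30, 31 and 32 before
    perfusion, labeling neurons 30–32 days old at perfusion.
    """

    injection_day_offsets: tuple[int, ...] = (30, 31, 32)
    injections_per_day: int = 3

    def __post_init__(self) -> None:
        offs = self.injection_day_offsets
        if len(offs) == 0:
            raise DesignError("empty injection schedule")
        if any(o <= 0 for o in offs):
            raise DesignError("injection day offsets must be positive")
        s = sorted(offs)
        if any(b - a != 1 for a, b in zip(s, s[1:])):
            raise DesignError("injection days must be consecutive")
        if self.injections_per_day < 1:
            raise DesignError("injections_per_day must be >= 1")


def human_equivalent_dose(d: DoseSpec) -> float:
    """Human-equivalent dose, mg/kg: animal dose × species factor."""
    return d.animal_dose * d.species_factor


def dose_ratio_to_child_range(d: DoseSpec) -> tuple[float, float]:
    """Human-equivalent dose as a multiple of each end of the pediatric
    dose range: ``(ratio to low end, ratio to high end)``."""
    hed = human_equivalent_dose(d)
    lo, hi = d.child_dose_range
    return (hed / lo, hed / hi)


def brdu_age_window(s: BrduSchedule) -> tuple[int, int]:
    """Cell-age window at perfusion, days: (min offset, max offset)."""
    offs = s.injection_day_offsets
    return (min(offs), max(offs))
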