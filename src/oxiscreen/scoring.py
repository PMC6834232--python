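"""Reference diagnosis from a scored respiratory-event list.

The rule set mirrors routine home-sleep-test practice: sleep apnea is an
apnea–hypopnea index (AHI) of at least 15 events per hour of sleep; it is
called *central* sleep apnea (CSA) when at least half of all scored
events carry a central mechanism, and *obstructive* (OSA) otherwise.
The 50% boundary belongs to CSA.  Sleep time is an input supplied by the
caller (no sleep staging happens here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .signal_io import RespiratoryEvent, validate_events

AHI_THRESHOLD = 15.0
CENTRAL_FRACTION_THRESHOLD = 0.5

LABELS = ("none", "CSA", "OSA")


@dataclass(frozen=True)
class SleepStudy:
    """Scored events plus the sleep duration they were observed over."""

    events: tuple[RespiratoryEvent, ...]
    sleep_hours: float

    def __post_init__(self) -> None:
        if self.sleep_hours <= 0:
            raise ValueError(f"sleep_hours must be > 0, got {self.sleep_hours}")
        object.__setattr__(
            self, "events", tuple(validate_events(list(self.events)))
        )


@dataclass(frozen=True)
class Diagnosis:
    ahi: float
    central_fraction: float | None  # None when there are no events
    label: str  # "none" | "CSA" | "OSA"


def round_half_up(x: float) -> int:
    """Round a nonnegative value half-up to the nearest integer."""
    if x < 0:
        raise ValueError("percentages are nonnegative")
    return int(math.floor(x + 0.5))


def compute_ahi(study: SleepStudy) -> float:
    """Apnea–hypopnea index: scored events per hour of sleep."""
    return len(study.events) / study.sleep_hours


def classify(study: SleepStudy) -> Diagnosis:
    """Apply the AHI>=15 / >=50%-central rule set to a sleep study."""
    ahi = compute_ahi(study)
    n = len(study.events)
    central_fraction = (
        sum(e.mechanism == "central" for e in study.events) / n if n else None
    )
    if ahi < AHI_THRESHOLD:
        label = "none"
    else:
        # ahi >= 15 with sleep_hours > 0 implies n >= 1, so the fraction exists
        assert central_fraction is not None
        label = (
            "CSA"
            if central_fraction >= CENTRAL_FRACTION_THRESHOLD
            else "OSA"
        )
    return Diagnosis(ahi=ahi, central_fraction=central_fraction, label=label)


def cohort_prevalence(
    diagnoses: Sequence[Diagnosis | str],
) -> tuple[int, int, int]:
    """Percentages of (any sleep apnea, CSA, OSA) over a cohort.

    Accepts Diagnosis objects or bare labels.  Percentages are rounded
    half-up to integers for reporting; before rounding, CSA% + OSA% equals
    the any-apnea percentage exactly.
    """
    if not diagnoses:
        raise ValueError("cohort_prevalence requires a nonempty list")
    labels = [d.label if isinstance(d, Diagnosis) else d for d in diagnoses]
    unknown = set(labels) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
    n = len(labels)
    n_csa = labels.count("CSA")
    n_osa = labels.count("OSA")
    return (
        round_half_up(100.0 * (n_csa + n_osa) / n),
        round_half_up(100.0 * n_csa / n),
        round_half_up(100.0 * n_osa / n),
    )
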