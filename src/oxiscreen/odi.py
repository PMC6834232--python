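"""Desaturation-dip detection and nightly oximetry summaries.

A *dip* is a maximal run of consecutive valid samples at or below
``baseline - min_drop`` whose span is at least ``min_duration`` seconds
(both thresholds inclusive).  The oxygen desaturation index (ODI) is the
number of such dips per hour of recording.

Two baseline conventions are supported, matching the two devices the
analysis is built around: a *fixed* baseline measured before the night
(the polygraph convention), and the mean saturation over the 11th minute
of recording (the app convention, minutes being counted from 1).

The drop threshold is in absolute percentage points — the standard
oximetry reading of "a >=3% decrease" — not a relative fraction of
baseline.  Invalid samples terminate a run by default (a dip is never
assumed to continue through a sensor dropout); short dropouts can be
bridged explicitly with ``bridge_gap_s`` for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import SpO2Trace, SPO2_MIN, SPO2_MAX

logger = logging.getLogger(__name__)

ELEVENTH_MINUTE_WINDOW = (600.0, 660.0)  # seconds from recording start


@dataclass(frozen=True)
class BaselineSpec:
    """How to obtain the reference saturation that dips are measured from.

    method="fixed" uses ``fixed_value`` (a pre-sleep spot measurement);
    method="eleventh_minute" averages valid samples whose onset falls in
    [600 s, 660 s) of the recording.
    """

    method: str  # "fixed" | "eleventh_minute"
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "eleventh_minute"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.method == "fixed":
            if self.fixed_value is None:
                raise ValueError("fixed baseline requires fixed_value")
            if not (SPO2_MIN <= self.fixed_value <= SPO2_MAX):
                raise ValueError(
                    f"fixed baseline must lie in [{SPO2_MIN}, {SPO2_MAX}]"
                )
        elif self.fixed_value is not None:
            raise ValueError("fixed_value is only meaningful with method='fixed'")


@dataclass(frozen=True)
class DesaturationDip:
    """One detected desaturation episode."""

    onset_s: float
    duration_s: float
    nadir: float  # lowest SpO2 within the dip, percent
    depth: float  # percentage points below baseline at the nadir

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class OximetrySummary:
    """Nightly summary statistics of one oximetry recording."""

    mean_spo2: float
    lowest_spo2: float
    pct_time_below_90: float
    odi: float  # dips per hour
    total_dips: int
    recording_hours: float
    baseline: float


class TraceTooShortError(ValueError):
    """Recording shorter than the window a baseline method requires."""


def compute_baseline(trace: SpO2Trace, spec: BaselineSpec) -> float:
    """Return the baseline saturation for ``trace`` under ``spec``.

    The eleventh-minute method refuses to fall back silently: a recording
    shorter than 11 minutes, or one with no valid sample in the window,
    raises instead of guessing.
    """
    if spec.method == "fixed":
        return float(spec.fixed_value)  # type: ignore[arg-type]

    lo, hi = ELEVENTH_MINUTE_WINDOW
    if trace.duration_s < hi:
        raise TraceTooShortError(
            f"eleventh-minute baseline needs >= {hi:.0f} s of recording, "
            f"trace has {trace.duration_s:.1f} s"
        )
    i0 = int(np.ceil(lo * trace.fs))
    i1 = int(np.ceil(hi * trace.fs))
    window = trace.values[i0:i1]
    ok = trace.valid_mask[i0:i1]
    if not ok.any():
        raise ValueError(
            "no valid samples in the 11th-minute window [600 s, 660 s)"
        )
    return float(window[ok].mean())


def _below_threshold(
    trace: SpO2Trace, baseline: float, min_drop: float, bridge_gap_s: float
) -> np.ndarray:
    below = trace.valid_mask & (trace.values <= baseline - min_drop)
    if bridge_gap_s > 0:
        max_gap = int(round(bridge_gap_s * trace.fs))
        invalid = ~trace.valid_mask
        edges = np.flatnonzero(np.diff(np.r_[0, invalid.astype(np.int8), 0]))
        for start, stop in zip(edges[::2], edges[1::2]):
            if (
                stop - start <= max_gap
                and start > 0
                and stop < below.size
                and below[start - 1]
                and below[stop]
            ):
                below[start:stop] = True
    return below


def detect_dips(
    trace: SpO2Trace,
    baseline: float,
    min_drop: float = 3.0,
    min_duration: float = 10.0,
    *,
    bridge_gap_s: float = 0.0,
) -> list[DesaturationDip]:
    """Detect desaturation dips against a baseline saturation.

    Returns maximal runs of samples ``<= baseline - min_drop`` spanning
    ``>= min_duration`` seconds, sorted by onset.  Maximality makes the
    returned dips pairwise non-overlapping.  A value exactly at
    ``baseline - min_drop`` is inside a dip and a run of exactly
    ``min_duration`` seconds qualifies (both bounds inclusive).
    """
    if not (SPO2_MIN <= baseline <= SPO2_MAX):
        raise ValueError(f"baseline {baseline} outside [{SPO2_MIN}, {SPO2_MAX}]")
    if min_drop <= 0 or min_duration <= 0:
        raise ValueError("min_drop and min_duration must be positive")
    if len(trace) and not trace.valid_mask.any():
        logger.warning("trace contains no valid samples; returning no dips")
        return []

    below = _below_threshold(trace, baseline, min_drop, bridge_gap_s)
    edges = np.flatnonzero(np.diff(np.r_[0, below.astype(np.int8), 0]))
    dips: list[DesaturationDip] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        span = (stop - start) / trace.fs
        if span < min_duration:
            continue
        seg = trace.values[start:stop]
        ok = trace.valid_mask[start:stop]
        nadir = float(seg[ok].min()) if ok.any() else float(seg.min())
        dips.append(
            DesaturationDip(
                onset_s=start / trace.fs,
                duration_s=span,
                nadir=nadir,
                depth=float(baseline - nadir),
            )
        )
    return dips


def compute_summary(
    trace: SpO2Trace,
    spec: BaselineSpec,
    min_drop: float = 3.0,
    min_duration: float = 10.0,
    *,
    use_valid_time: bool = False,
    bridge_gap_s: float = 0.0,
) -> OximetrySummary:
    """Nightly summary: mean/lowest SpO2, % time < 90%, dip count and ODI.

    Mean, lowest and the <90% fraction are computed over valid samples
    only.  The ODI denominator is the total recording span by default;
    ``use_valid_time`` switches it to the valid (non-dropout) time.
    """
    if len(trace) == 0 or not trace.valid_mask.any():
        raise ValueError("summary requires at least one valid sample")
    baseline = compute_baseline(trace, spec)
    dips = detect_dips(
        trace, baseline, min_drop, min_duration, bridge_gap_s=bridge_gap_s
    )
    valid_vals = trace.values[trace.valid_mask]
    if use_valid_time:
        hours = trace.n_valid / trace.fs / 3600.0
    else:
        hours = trace.duration_s / 3600.0
    return OximetrySummary(
        mean_spo2=float(valid_vals.mean()),
        lowest_spo2=float(valid_vals.min()),
        pct_time_below_90=float(100.0 * (valid_vals < 90).mean()),
        odi=len(dips) / hours,
        total_dips=len(dips),
        recording_hours=hours,
        baseline=baseline,
    )
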