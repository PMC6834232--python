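"""Synthetic overnight oximetry with ground-truth event annotations.

No public overnight SpO2 recordings exist for the screening design this
package analyses, so every downstream stage is exercised on generated
nights that carry their own ground truth.  A patient is described by a
phenotype — ``none`` (no sleep apnea), ``central`` (periodic
crescendo–decrescendo desaturation trains, the Cheyne-Stokes pattern
common in heart failure) or ``obstructive`` (irregularly spaced
desaturation clusters) — plus a stable baseline saturation, an event
rate, and event depth/duration distributions.

Each planted respiratory event is rendered as a piecewise-linear
desaturation: a 10–14 s descent from baseline to ``baseline - depth``, a
plateau at the nadir for the event's stated duration, and a 10–14 s
recovery.  Event onsets, durations and ramps are aligned to whole
seconds, so a noise-free night analysed at 8 Hz and its 1 Hz decimation
contain identical below-threshold runs.  Events start only after the
12th minute, leaving the 11th-minute baseline window undisturbed.

Device imperfections are layered on top of the clean rendering:
additive Gaussian noise (rounded to the integer percent a pulse oximeter
reports, clipped to [50, 100]) and dropout segments with exponential
lengths.  The same seed always reproduces the same night bit-for-bit,
and the underlying event plan depends only on (profile, seed) — not on
the sampling rate or noise settings — so an 8 Hz polygraph trace and a
1 Hz app trace of the same night share one event sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import scoring
from .signal_io import RespiratoryEvent, SpO2Trace, SPO2_MIN
from datetime import datetime

PHENOTYPES = ("none", "central", "obstructive")
ALLOWED_FS = (1, 8)

#: events may not start before this, keeping the 11th-minute window clean
EVENT_FREE_HEAD_S = 720
#: events must end at least this long before the recording stops
TAIL_GUARD_S = 60
#: descent/recovery ramps are drawn uniformly from this range (whole seconds)
RAMP_RANGE_S = (10, 14)

DEFAULT_NOISE_SIGMA = 0.5
DROPOUT_MEAN_S = 30.0
HYPOPNEA_PROB = 0.6


@dataclass(frozen=True)
class PatientProfile:
    """Generative description of one patient's night.

    ``event_rate`` is in events per hour of sleep; ``event_depth_mean``
    in percentage points (>= 3 so every event can qualify as a dip);
    ``event_duration_mean`` in seconds (>= 10); ``cycle_length`` is the
    Cheyne-Stokes period in seconds and only matters for the central
    phenotype; ``artifact_rate`` is dropout segments per hour.
    """

    phenotype: str
    baseline_spo2: int = 96
    event_rate: float = 0.0
    event_depth_mean: float = 5.0
    event_duration_mean: float = 25.0
    cycle_length: float = 60.0
    sleep_hours: float = 7.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if not (90 <= self.baseline_spo2 <= 99):
            raise ValueError("baseline_spo2 must be an integer in [90, 99]")
        if self.event_rate < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.event_rate > 0 and self.event_depth_mean < 3:
            raise ValueError("event_depth_mean must be >= 3 percentage points")
        if self.event_rate > 0 and self.event_duration_mean < 10:
            raise ValueError("event_duration_mean must be >= 10 s")
        if self.phenotype == "central" and not (45 <= self.cycle_length <= 90):
            raise ValueError("cycle_length must lie in [45, 90] s")
        if not (4 <= self.sleep_hours <= 10):
            raise ValueError("sleep_hours must lie in [4, 10]")


#: realistic per-phenotype defaults for cohort simulation: heart-failure
#: CSA nights show dense periodic events (~30/h at a ~60 s cycle) of
#: moderate depth; OSA nights show fewer, deeper, longer events; apnea-free
#: nights still have sporadic shallow desaturations well below AHI 15.
PHENOTYPE_DEFAULTS: dict[str, PatientProfile] = {
    "central": PatientProfile(
        phenotype="central",
        event_rate=30.0,
        event_depth_mean=5.0,
        event_duration_mean=22.0,
        cycle_length=60.0,
    ),
    "obstructive": PatientProfile(
        phenotype="obstructive",
        event_rate=25.0,
        event_depth_mean=7.0,
        event_duration_mean=30.0,
    ),
    "none": PatientProfile(
        phenotype="none",
        event_rate=4.0,
        event_depth_mean=4.0,
        event_duration_mean=15.0,
    ),
}

#: fraction of events carrying a central mechanism, by phenotype; applied
#: deterministically (ceil for central, floor otherwise) so the >=50% /
#: <50% diagnostic rule holds on every draw, not just in expectation
CENTRAL_MECH_FRACTION = {"central": 0.85, "obstructive": 0.15, "none": 0.15}


@dataclass(frozen=True)
class PlannedEvent:
    onset_s: int
    ramp_down_s: int
    plateau_s: int
    ramp_up_s: int
    depth: int
    type: str
    mechanism: str

    @property
    def end_s(self) -> int:
        return self.onset_s + self.ramp_down_s + self.plateau_s + self.ramp_up_s


@dataclass
class GroundTruth:
    """What was actually planted in a generated night."""

    events: list[RespiratoryEvent]
    true_odi_poly: float  # planted dips per hour on the clean trace
    true_diagnosis: str  # "none" | "CSA" | "OSA", by the scoring rules
    baseline_spo2: int
    sleep_hours: float
    clipped_events: list[int] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _plan_events(
    profile: PatientProfile, rng: np.random.Generator
) -> tuple[list[PlannedEvent], list[int]]:
    """Lay out the night's desaturation events on an integer-second grid."""
    span = int(round(profile.sleep_hours * 3600))
    usable_end = span - TAIL_GUARD_S
    if profile.event_rate == 0 or usable_end <= EVENT_FREE_HEAD_S:
        return [], []

    n_target = rng.poisson(profile.event_rate * profile.sleep_hours)
    events: list[PlannedEvent] = []
    clipped: list[int] = []
    t = float(EVENT_FREE_HEAD_S)
    if profile.phenotype == "central":
        # one periodic Cheyne-Stokes train; random offset uses up slack
        mean_footprint = profile.event_duration_mean + 2 * RAMP_RANGE_S[1]
        slack = usable_end - EVENT_FREE_HEAD_S - n_target * max(
            profile.cycle_length * 1.1, mean_footprint
        )
        if slack > 0:
            t += float(rng.uniform(0, slack))

    while len(events) < n_target:
        ramp_down = int(rng.integers(RAMP_RANGE_S[0], RAMP_RANGE_S[1] + 1))
        ramp_up = int(rng.integers(RAMP_RANGE_S[0], RAMP_RANGE_S[1] + 1))
        if profile.phenotype == "central":
            # plateau bounded so consecutive cycles never merge
            max_plateau = int(0.9 * profile.cycle_length) - ramp_down - ramp_up - 2
            plateau = int(
                np.clip(
                    round(rng.normal(profile.event_duration_mean, 4.0)),
                    10,
                    max(10, max_plateau),
                )
            )
        else:
            plateau = int(
                max(10, round(rng.normal(profile.event_duration_mean, 5.0)))
            )
        depth = int(max(3, round(rng.normal(profile.event_depth_mean, 1.0))))
        if profile.baseline_spo2 - depth < SPO2_MIN:
            depth = profile.baseline_spo2 - SPO2_MIN
            clipped.append(len(events))

        onset = int(round(t))
        total = ramp_down + plateau + ramp_up
        if onset + total > usable_end:
            break  # night is full; remaining target events are dropped
        mech_placeholder = "central"  # reassigned below
        events.append(
            PlannedEvent(
                onset_s=onset,
                ramp_down_s=ramp_down,
                plateau_s=plateau,
                ramp_up_s=ramp_up,
                depth=depth,
                type="hypopnea" if rng.random() < HYPOPNEA_PROB else "apnea",
                mechanism=mech_placeholder,
            )
        )
        if profile.phenotype == "central":
            t = onset + profile.cycle_length * float(rng.uniform(0.9, 1.1))
            t = max(t, onset + total + 2)
        else:
            mean_gap = max(5.0, 3600.0 / profile.event_rate - total - 25.0)
            t = onset + total + 25 + float(rng.exponential(mean_gap))

    # deterministic mechanism mix so the diagnostic rule holds on every draw
    n = len(events)
    frac = CENTRAL_MECH_FRACTION[profile.phenotype]
    n_central = math.ceil(frac * n) if profile.phenotype == "central" else math.floor(frac * n)
    central_idx = set(rng.choice(n, size=n_central, replace=False)) if n else set()
    events = [
        replace(e, mechanism="central" if i in central_idx else "obstructive")
        for i, e in enumerate(events)
    ]
    return events, clipped


def _render_clean(
    profile: PatientProfile, plan: list[PlannedEvent], fs: int
) -> np.ndarray:
    """Render the noise-free saturation signal at ``fs`` Hz (float)."""
    n = int(round(profile.sleep_hours * 3600 * fs))
    sig = np.full(n, float(profile.baseline_spo2))
    base = float(profile.baseline_spo2)
    for ev in plan:
        lo = base - ev.depth
        i0 = ev.onset_s * fs
        i1 = i0 + ev.ramp_down_s * fs
        i2 = i1 + ev.plateau_s * fs
        i3 = i2 + ev.ramp_up_s * fs
        # descent reaches the nadir at i1; recovery leaves it after i2
        sig[i0:i1] = np.linspace(base, lo, i1 - i0, endpoint=False)
        sig[i1:i2] = lo
        sig[i2:i3] = np.linspace(lo, base, i3 - i2, endpoint=False)
    return sig


def generate_trace(
    profile: PatientProfile,
    fs: int,
    seed: int,
    *,
    device: str | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    artifact_rate: float | None = None,
) -> tuple[SpO2Trace, GroundTruth]:
    """Generate one night of oximetry plus its ground truth.

    The event plan is a function of (profile, seed) only; noise and
    dropouts are drawn from a stream keyed additionally by ``fs``, so the
    1 Hz and 8 Hz renderings of the same seed describe the same night
    through different devices.  ``artifact_rate`` overrides the profile's
    dropout rate (e.g. 0 for the hospital-grade device).
    """
    if fs not in ALLOWED_FS:
        raise ValueError(f"fs must be one of {ALLOWED_FS} Hz, got {fs}")
    plan, clipped = _plan_events(profile, np.random.default_rng([seed, 0]))
    sig = _render_clean(profile, plan, fs)

    dev_rng = np.random.default_rng([seed, fs])
    if noise_sigma > 0:
        sig = sig + dev_rng.normal(0.0, noise_sigma, size=sig.size)
    values = np.clip(np.rint(sig), SPO2_MIN, 100.0)

    mask = np.ones(sig.size, dtype=bool)
    a_rate = profile.artifact_rate if artifact_rate is None else artifact_rate
    if a_rate > 0:
        n_drop = dev_rng.poisson(a_rate * profile.sleep_hours)
        for _ in range(n_drop):
            start = int(dev_rng.integers(0, sig.size))
            length = max(1, int(round(dev_rng.exponential(DROPOUT_MEAN_S) * fs)))
            mask[start : start + length] = False

    trace = SpO2Trace(
        device=device or ("app" if fs == 1 else "polygraph"),
        fs=fs,
        start_time=datetime(2000, 1, 1, 23, 0, 0),
        values=values,
        valid_mask=mask,
    )
    events = [
        RespiratoryEvent(
            onset_s=float(e.onset_s),
            duration_s=float(e.ramp_down_s + e.plateau_s + e.ramp_up_s),
            type=e.type,
            mechanism=e.mechanism,
        )
        for e in plan
    ]
    diagnosis = scoring.classify(
        scoring.SleepStudy(events=tuple(events), sleep_hours=profile.sleep_hours)
    )
    truth = GroundTruth(
        events=events,
        true_odi_poly=len(plan) / profile.sleep_hours,
        true_diagnosis=diagnosis.label,
        baseline_spo2=profile.baseline_spo2,
        sleep_hours=profile.sleep_hours,
        clipped_events=clipped,
    )
    return trace, truth


@dataclass
class CohortPatient:
    patient_id: str
    profile: PatientProfile
    poly_trace: SpO2Trace  # 8 Hz, low-noise, no dropouts
    app_trace: SpO2Trace  # 1 Hz, device noise and dropouts
    truth: GroundTruth


def generate_cohort(
    n_patients: int,
    prevalence_csa: float,
    prevalence_osa: float,
    seed: int,
    *,
    sleep_hours: float | None = None,
    app_noise_sigma: float = DEFAULT_NOISE_SIGMA,
    poly_noise_sigma: float = 0.2,
    app_artifact_rate: float = 0.3,
) -> list[CohortPatient]:
    """Simulate a screening cohort measured by both devices in one night.

    Phenotypes are drawn i.i.d. with the given prevalences; each patient's
    polygraph (8 Hz) and app (1 Hz) traces share a single underlying event
    sequence, with independent device noise, and dropouts only on the app
    side.  Baseline saturation varies across patients in 93–97%.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for name, p in (("prevalence_csa", prevalence_csa), ("prevalence_osa", prevalence_osa)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if prevalence_csa + prevalence_osa > 1 + 1e-12:
        raise ValueError("prevalences must sum to at most 1")

    rng = np.random.default_rng(seed)
    cohort: list[CohortPatient] = []
    for i in range(n_patients):
        u = rng.random()
        if u < prevalence_csa:
            phenotype = "central"
        elif u < prevalence_csa + prevalence_osa:
            phenotype = "obstructive"
        else:
            phenotype = "none"
        profile = replace(
            PHENOTYPE_DEFAULTS[phenotype],
            baseline_spo2=int(rng.integers(93, 98)),
            artifact_rate=app_artifact_rate,
            **({"sleep_hours": sleep_hours} if sleep_hours is not None else {}),
        )
        patient_seed = int(rng.integers(0, 2**31 - 1))
        poly_trace, truth = generate_trace(
            profile, 8, patient_seed,
            noise_sigma=poly_noise_sigma, artifact_rate=0.0,
        )
        app_trace, _ = generate_trace(
            profile, 1, patient_seed, noise_sigma=app_noise_sigma
        )
        cohort.append(
            CohortPatient(
                patient_id=f"P{i + 1:03d}",
                profile=profile,
                poly_trace=poly_trace,
                app_trace=app_trace,
                truth=truth,
            )
        )
    return cohort
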