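"""End-to-end study orchestration.

Two entry points:

* :func:`reference_study_report` rebuilds the published screening study's
  endpoint statistics from a packaged per-patient fixture — 24 patients
  with a polygraph diagnosis, 22 of whom also transferred a first-night
  app recording.  The fixture's per-patient ODI values are synthetic
  stand-ins (only the diagnosis labels and the above/below-15 screen
  calls are constrained by the published marginal tables, which do not
  identify individual patients); every reconstructed 2x2 table matches
  the published one cell for cell.
* :func:`run_synthetic_study` runs the whole screening analysis on a
  generated cohort: simulate both devices' nights, compute the app ODI
  against the eleventh-minute baseline and the polygraph ODI against the
  fixed pre-sleep baseline, classify each patient from the scored events,
  and tabulate screen-vs-reference agreement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import scoring
from .agreement import (
    AgreementStats,
    ContingencyTable2x2,
    PowerParams,
    build_table,
    diagnostic_metrics,
    mcnemar_sample_size,
)
from .odi import BaselineSpec, TraceTooShortError, compute_summary
from .synthetic import generate_cohort

FIXTURE_NAME = "study_cohort_synthetic.csv"
FIXTURE_SHA256 = "982f5f383785fa7f2c5ccc4d3ebc7773344c40f29c3f41abb87986f83a263738"

TABLE_KEYS = ("mobile_vs_csa", "mobile_vs_any", "poly_vs_csa", "poly_vs_any")


@dataclass
class StudyReport:
    """Agreement tables, per-table statistics and cohort prevalence."""

    tables: dict[str, ContingencyTable2x2]
    stats: dict[str, AgreementStats]
    prevalence: tuple[int, int, int]  # % any sleep apnea, % CSA, % OSA
    power_n: int  # pairs required by the McNemar power calculation
    n_analyzable: int
    n_cohort: int
    exclusions: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tables": {k: asdict(t) for k, t in self.tables.items()},
            "stats": {k: asdict(s) for k, s in self.stats.items()},
            "prevalence": {
                "any_sleep_apnea_pct": self.prevalence[0],
                "csa_pct": self.prevalence[1],
                "osa_pct": self.prevalence[2],
            },
            "power_n": self.power_n,
            "n_analyzable": self.n_analyzable,
            "n_cohort": self.n_cohort,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def load_study_fixture() -> pd.DataFrame:
    """Load the packaged per-patient fixture, verifying its checksum."""
    ref = resources.files("oxiscreen").joinpath("data", FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise RuntimeError(
            f"fixture {FIXTURE_NAME} checksum mismatch ({digest}); "
            "refusing to report statistics from a modified fixture"
        )
    return pd.read_csv(pd.io.common.BytesIO(raw))


def _tabulate(
    records: list[tuple[str, float, float]],
    threshold: float,
    method: str,
) -> tuple[dict[str, ContingencyTable2x2], dict[str, AgreementStats]]:
    """Build the four screen-vs-reference tables from analyzable patients.

    ``records`` holds (diagnosis label, mobile ODI, polygraph ODI).
    """
    tables = {
        "mobile_vs_csa": build_table(
            [(dx == "CSA", mob) for dx, mob, _ in records], threshold
        ),
        "mobile_vs_any": build_table(
            [(dx != "none", mob) for dx, mob, _ in records], threshold
        ),
        "poly_vs_csa": build_table(
            [(dx == "CSA", pol) for dx, _, pol in records], threshold
        ),
        "poly_vs_any": build_table(
            [(dx != "none", pol) for dx, _, pol in records], threshold
        ),
    }
    stats = {k: diagnostic_metrics(t, method) for k, t in tables.items()}
    return tables, stats


def reference_study_report(
    threshold: float = 15.0, method: str = "exact"
) -> StudyReport:
    """Recompute the published endpoint statistics from the fixture.

    Patients without a first-night app recording are excluded from the
    agreement tables but still count toward cohort prevalence, mirroring
    the study's exclusion flow.
    """
    df = load_study_fixture()
    analyzable = df.dropna(subset=["mobile_odi", "polygraph_odi"])
    excluded = df[df["mobile_odi"].isna() | df["polygraph_odi"].isna()]
    records = [
        (row.polygraph_diagnosis, float(row.mobile_odi), float(row.polygraph_odi))
        for row in analyzable.itertuples()
    ]
    tables, stats = _tabulate(records, threshold, method)
    prevalence = scoring.cohort_prevalence(list(df["polygraph_diagnosis"]))
    return StudyReport(
        tables=tables,
        stats=stats,
        prevalence=prevalence,
        power_n=mcnemar_sample_size(PowerParams()),
        n_analyzable=len(analyzable),
        n_cohort=len(df),
        exclusions=[
            f"{row.patient_id}: no first-night app recording"
            for row in excluded.itertuples()
        ],
        provenance={"source": FIXTURE_NAME, "sha256": FIXTURE_SHA256},
    )


@dataclass
class CohortConfig:
    """Cohort composition and detector settings for a synthetic study.

    Defaults mirror the reference study's analyzable cohort: 22 patients
    of whom 7 had central and 6 obstructive sleep apnea.
    """

    n_patients: int = 22
    prevalence_csa: float = 7 / 22
    prevalence_osa: float = 6 / 22
    sleep_hours: float | None = None  # None = per-phenotype default (7 h)
    threshold: float = 15.0
    min_drop: float = 3.0
    min_duration: float = 10.0
    app_noise_sigma: float = 0.5
    poly_noise_sigma: float = 0.2
    app_artifact_rate: float = 0.3
    mcnemar_method: str = "exact"

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        for name in ("prevalence_csa", "prevalence_osa"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{name} must lie in [0, 1]")
        if self.prevalence_csa + self.prevalence_osa > 1 + 1e-12:
            problems.append("prevalence_csa + prevalence_osa must be <= 1")
        if self.threshold <= 0:
            problems.append("threshold must be positive")
        if self.min_drop <= 0 or self.min_duration <= 0:
            problems.append("min_drop and min_duration must be positive")
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_synthetic_study(config: CohortConfig, seed: int) -> StudyReport:
    """Simulate a cohort and push every patient through the full analysis.

    The polygraph ODI uses the fixed pre-sleep baseline (the patient's
    known stable saturation); the app ODI uses the eleventh-minute
    baseline.  Patients whose app recording cannot support that baseline
    (too short, or no valid sample in the window) are excluded and logged.
    The reference diagnosis comes from the scored ground-truth events.
    """
    config.validate()
    cohort = generate_cohort(
        config.n_patients,
        config.prevalence_csa,
        config.prevalence_osa,
        seed,
        sleep_hours=config.sleep_hours,
        app_noise_sigma=config.app_noise_sigma,
        poly_noise_sigma=config.poly_noise_sigma,
        app_artifact_rate=config.app_artifact_rate,
    )
    records: list[tuple[str, float, float]] = []
    labels: list[str] = []
    exclusions: list[str] = []
    for patient in cohort:
        study = scoring.SleepStudy(
            events=tuple(patient.truth.events),
            sleep_hours=patient.truth.sleep_hours,
        )
        label = scoring.classify(study).label
        labels.append(label)
        try:
            app_summary = compute_summary(
                patient.app_trace,
                BaselineSpec(method="eleventh_minute"),
                config.min_drop,
                config.min_duration,
            )
        except (TraceTooShortError, ValueError) as exc:
            exclusions.append(f"{patient.patient_id}: {exc}")
            continue
        poly_summary = compute_summary(
            patient.poly_trace,
            BaselineSpec(method="fixed", fixed_value=patient.truth.baseline_spo2),
            config.min_drop,
            config.min_duration,
        )
        records.append((label, app_summary.odi, poly_summary.odi))

    if not records:
        raise RuntimeError("every patient was excluded; no analyzable data")
    tables, stats = _tabulate(records, config.threshold, config.mcnemar_method)
    return StudyReport(
        tables=tables,
        stats=stats,
        prevalence=scoring.cohort_prevalence(labels),
        power_n=mcnemar_sample_size(PowerParams()),
        n_analyzable=len(records),
        n_cohort=len(cohort),
        exclusions=exclusions,
        provenance={"seed": seed, "config_sha256": config.digest()},
    )
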