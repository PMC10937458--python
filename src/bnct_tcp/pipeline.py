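"""End-to-end TCP pipeline: weighted-dose DVH -> EQD2 DVH -> gEUD -> TCP -> class.

For each tumor target the weighted-dose DVH is converted bin by bin to
EQD2 under the USC model, reduced to gEUD with the tumor exponent, pushed
through the logistic dose-response, and the resulting TCP is mapped onto a
response level.  Reports carry the per-target minimum weighted dose, which
for negative gEUD exponents is the main driver of the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import dvh as dvh_mod
from .dose import eqd2_dvh
from .dvh import DVH
from .survival import SCC_USC_PARAMS, SurvivalParamsUSC
from .tcp import SCC_TCP_PARAMS, ResponseClass, TCPParams, classify_response, geud, tcp_from_geud

__all__ = [
    "PipelineConfig",
    "PatientRecord",
    "Target",
    "TargetResult",
    "TCPReport",
    "CohortResult",
    "PipelineError",
    "run_patient",
    "run_cohort",
    "format_report",
    "HN_COHORT_REFERENCE",
]

OBSERVED_RESPONSES = ("CR", "PR", "SD", "PD")


class PipelineError(RuntimeError):
    """A per-target failure annotated with patient/target context."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the procedure needs: survival-curve coefficients for the
    EQD2 conversion, TCP parameters, and the number of BNCT fractions the
    DVH bin doses represent (bin doses are per-fraction)."""

    survival: SurvivalParamsUSC = SCC_USC_PARAMS
    tcp: TCPParams = SCC_TCP_PARAMS
    fractions: int = 1

    def __post_init__(self):
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")


@dataclass(frozen=True)
class Target:
    label: str
    dvh: DVH


@dataclass(frozen=True)
class PatientRecord:
    """One patient: id, >=1 uniquely labelled tumor targets (weighted-dose
    DVHs), and optionally the observed RECIST response."""

    patient_id: str
    targets: tuple
    observed_response: Optional[str] = None

    def __post_init__(self):
        targets = tuple(
            t if isinstance(t, Target) else Target(*t) for t in self.targets
        )
        if not targets:
            raise ValueError("patient must have at least one target")
        labels = [t.label for t in targets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate target labels for patient {self.patient_id}")
        if self.observed_response is not None and self.observed_response not in OBSERVED_RESPONSES:
            raise ValueError(f"observed_response must be one of {OBSERVED_RESPONSES}")
        object.__setattr__(self, "targets", targets)


@dataclass(frozen=True)
class TargetResult:
    label: str
    d_bnct_min: float  # Gy-w
    geud: float  # Gy (EQD2)
    tcp: float  # percent
    response_class: ResponseClass
    eqd2: DVH = field(repr=False)

    def __post_init__(self):
        if not (0 <= self.tcp <= 100):
            raise ValueError("tcp must lie in [0, 100]")
        lo, hi = dvh_mod.min_dose(self.eqd2), dvh_mod.max_dose(self.eqd2)
        if not (lo - 1e-9 <= self.geud <= hi + 1e-9):
            raise ValueError("gEUD must lie within [min, max] of the EQD2 DVH")


@dataclass(frozen=True)
class TCPReport:
    patient_id: str
    targets: tuple  # of TargetResult
    observed_response: Optional[str] = None

    def rows(self) -> list[dict]:
        return [
            {
                "patient_id": self.patient_id,
                "target": t.label,
                "d_bnct_min_gyw": t.d_bnct_min,
                "geud_gy": t.geud,
                "tcp_pct": t.tcp,
                "response_class": t.response_class.value,
                "observed_response": self.observed_response,
            }
            for t in self.targets
        ]


def run_patient(rec: PatientRecord, config: PipelineConfig = PipelineConfig()) -> TCPReport:
    """Run the two-step procedure (EQD2 conversion, then gEUD -> TCP) for
    every target of one patient."""
    results = []
    for target in rec.targets:
        try:
            eqd2 = eqd2_dvh(target.dvh, config.survival, config.fractions)
            g = geud(eqd2, config.tcp.a)
            tcp = tcp_from_geud(g, config.tcp)
            results.append(
                TargetResult(
                    label=target.label,
                    d_bnct_min=dvh_mod.min_dose(target.dvh),
                    geud=g,
                    tcp=tcp,
                    response_class=classify_response(tcp),
                    eqd2=eqd2,
                )
            )
        except (ValueError, NotImplementedError) as err:
            raise PipelineError(
                f"patient {rec.patient_id!r} target {target.label!r}: {err}"
            ) from err
    return TCPReport(
        patient_id=rec.patient_id,
        targets=tuple(results),
        observed_response=rec.observed_response,
    )


@dataclass
class CohortResult:
    table: pd.DataFrame
    summary: dict
    failures: list  # of (patient_id, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_cohort(
    records: Sequence[PatientRecord], config: PipelineConfig = PipelineConfig()
) -> CohortResult:
    """Run every patient, collecting per-patient failures without aborting.

    Returns one table row per (patient, target) plus a summary of response-
    class counts; ``failures`` lists patients whose processing raised.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")
    rows, failures = [], []
    for rec in records:
        try:
            rows.extend(run_patient(rec, config).rows())
        except PipelineError as err:
            failures.append((rec.patient_id, str(err)))
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "target",
            "d_bnct_min_gyw",
            "geud_gy",
            "tcp_pct",
            "response_class",
            "observed_response",
        ],
    )
    counts = table["response_class"].value_counts().to_dict()
    summary = {
        "n_patients": len(records),
        "n_targets": len(table),
        "n_failed_patients": len(failures),
        "response_class_counts": {c.value: counts.get(c.value, 0) for c in ResponseClass},
    }
    return CohortResult(table=table, summary=summary, failures=failures)


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def format_report(result: CohortResult, decimals: int = 1) -> pd.DataFrame:
    """Reporting-layer copy of the cohort table with half-up rounding.

    Rounding happens only here; internal values are never rounded.
    """
    out = result.table.copy()
    for col in ("d_bnct_min_gyw", "geud_gy", "tcp_pct"):
        out[col] = out[col].map(lambda v: _round_half_up(v, decimals))
    return out


#: Published per-target results for the 11-patient recurrent head-and-neck
#: SCC cohort (two-fraction BNCT clinical trial) against which the TCP model
#: was validated: (patient, target, minimum weighted dose [Gy-w],
#: gEUD [Gy, EQD2], TCP [%], observed RECIST response).  gEUD and TCP are
#: as printed (3 significant figures / 1 decimal), so recomputing TCP from
#: the printed gEUD can differ from the printed TCP by ~0.1 pp.
HN_COHORT_REFERENCE = (
    ("1", "GTV1", 6.0, 21.5, 0.2, "PD"),
    ("1", "GTV2", 15.3, 47.2, 51.6, "PD"),
    ("2", "GTV1", 6.5, 21.1, 0.2, "SD"),
    ("3", "GTV1", 10.0, 42.3, 30.8, "PR"),
    ("4", "GTV1", 12.3, 41.0, 25.9, "PR"),
    ("5", "GTV1", 9.2, 31.9, 4.4, "SD"),
    ("6", "GTV1", 19.5, 68.6, 95.5, "CR"),
    ("7", "GTV1", 7.0, 22.4, 0.3, "PD"),
    ("7", "GTV2", 22.3, 63.6, 92.0, "PD"),
    ("8", "GTV1", 25.3, 80.7, 98.7, "CR"),
    ("8", "GTV2", 19.0, 56.5, 81.8, "CR"),
    ("9", "GTV1", 18.5, 49.8, 62.3, "CR"),
    ("10", "GTV1", 9.4, 44.7, 40.9, "PR"),
    ("11", "GTV1", 7.9, 35.7, 10.3, "PD"),
)
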