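"""Screening statistics for validating classifier output against self-report.

The 2×2 cross-tabulation is stored with the tool's call on the rows and the
self-reported truth on the columns:

    a = (tool non-veteran, true non-veteran)    b = (tool non-veteran, true veteran)
    c = (tool veteran,     true non-veteran)    d = (tool veteran,     true veteran)

Two sensitivity/specificity conventions are computed and labeled, never
conflated. The *study convention* treats detection of non-veterans as
"sensitivity" (a/(a+c)) and recovery of veterans as "specificity" (d/(b+d))
— the definitions under which a validation survey dominated by non-veterans
reads naturally. The *veteran-positive convention* is the conventional
epidemiological one (sensitivity d/(b+d), specificity a/(a+c)); swapping the
convention flag swaps the two values exactly. The Youden index J =
sensitivity + specificity − 1 is identical under both conventions and is a
distinct quantity from percent agreement (a+d)/n; the two must never be
interchanged. Statistics with a zero denominator are reported as undefined
(None), not as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus_io import CohortFlow, PatientRecord
from .ml_classifier import PatientDecision


class EvaluationError(ValueError):
    """Raised on unmatched ids, duplicate patients, or an empty table."""


@dataclass(frozen=True)
class ConfusionMatrix:
    a: int  # tool non-veteran, true non-veteran
    b: int  # tool non-veteran, true veteran
    c: int  # tool veteran,     true non-veteran
    d: int  # tool veteran,     true veteran

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def predicted_veteran(self) -> int:
        return self.c + self.d

    @property
    def predicted_non_veteran(self) -> int:
        return self.a + self.b

    @property
    def true_veteran(self) -> int:
        return self.b + self.d

    @property
    def true_non_veteran(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class ValidationReport:
    """All screening statistics from one 2×2 table, unrounded.

    ``sensitivity`` / ``specificity`` / ``youden_j`` follow the declared
    ``positive_class_convention`` ("study" = non-veteran detection read as
    sensitivity; "veteran_positive" = conventional). The explicitly suffixed
    fields carry both variants regardless of the flag. Rounding happens only
    at the presentation layer.
    """

    n: int
    agreement: float
    ppv_veteran: float | None
    npv_veteran: float | None
    sensitivity_study: float | None
    specificity_study: float | None
    sensitivity_std: float | None
    specificity_std: float | None
    youden_j: float | None
    positive_class_convention: str = "study"

    @property
    def sensitivity(self) -> float | None:
        return (self.sensitivity_study if self.positive_class_convention == "study"
                else self.sensitivity_std)

    @property
    def specificity(self) -> float | None:
        return (self.specificity_study if self.positive_class_convention == "study"
                else self.specificity_std)


def cross_tabulate(
    predictions: Sequence[PatientDecision], truth: Sequence[PatientRecord]
) -> ConfusionMatrix:
    """Join predictions to ground truth by patient_id and count the 2×2 cells."""
    truth_by_id: dict[str, int] = {}
    for rec in truth:
        if rec.patient_id in truth_by_id:
            raise EvaluationError(f"duplicate patient_id in truth: {rec.patient_id!r}")
        if rec.self_report is None:
            raise EvaluationError(f"patient {rec.patient_id!r} has no self_report label")
        truth_by_id[rec.patient_id] = rec.self_report

    a = b = c = d = 0
    seen: set[str] = set()
    for pred in predictions:
        if pred.patient_id in seen:
            raise EvaluationError(f"duplicate patient_id in predictions: {pred.patient_id!r}")
        seen.add(pred.patient_id)
        if pred.patient_id not in truth_by_id:
            raise EvaluationError(f"no ground truth for patient {pred.patient_id!r}")
        true_vet = truth_by_id[pred.patient_id]
        if pred.label == 0:
            if true_vet == 0:
                a += 1
            else:
                b += 1
        else:
            if true_vet == 0:
                c += 1
            else:
                d += 1
    return ConfusionMatrix(a=a, b=b, c=c, d=d)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def validation_report(m: ConfusionMatrix, convention: str = "study") -> ValidationReport:
    """Compute all screening statistics from a 2×2 table.

    Raises :class:`EvaluationError` on an empty table. Any statistic whose
    denominator is zero comes back as None (undefined), never 0.
    """
    if convention not in ("study", "veteran_positive"):
        raise ValueError(f"unknown convention {convention!r}")
    if m.n == 0:
        raise EvaluationError("cannot evaluate an empty confusion matrix")

    sens_study = _ratio(m.a, m.a + m.c)
    spec_study = _ratio(m.d, m.b + m.d)
    youden = (
        sens_study + spec_study - 1.0
        if sens_study is not None and spec_study is not None
        else None
    )
    return ValidationReport(
        n=m.n,
        agreement=(m.a + m.d) / m.n,
        ppv_veteran=_ratio(m.d, m.c + m.d),
        npv_veteran=_ratio(m.a, m.a + m.b),
        sensitivity_study=sens_study,
        specificity_study=spec_study,
        sensitivity_std=spec_study,
        specificity_std=sens_study,
        youden_j=youden,
        positive_class_convention=convention,
    )


@dataclass(frozen=True)
class FlowPercentage:
    stage_name: str
    count_in: int
    count_out: int
    percent: float | None  # 100 * out / in at 1 dp; None when count_in == 0


def flow_percentages(flow: Sequence[CohortFlow]) -> list[FlowPercentage]:
    """Percent retained at each stage of a chained cohort flow, at 1 dp."""
    for prev, nxt in zip(flow, flow[1:]):
        if nxt.count_in != prev.count_out:
            raise EvaluationError(
                f"flow not chained at {nxt.stage_name!r}: "
                f"{nxt.count_in} != {prev.count_out}"
            )
    return [
        FlowPercentage(
            stage_name=s.stage_name,
            count_in=s.count_in,
            count_out=s.count_out,
            percent=round(100.0 * s.count_out / s.count_in, 1) if s.count_in else None,
        )
        for s in flow
    ]


def format_table(m: ConfusionMatrix) -> str:
    """Human-readable 2×2 table (tool rows × self-report columns)."""
    rows = [
        ("Outcome", "True Non-Veteran", "True Veteran", "Total"),
        ("Tool Non-veteran", str(m.a), str(m.b), str(m.predicted_non_veteran)),
        ("Tool Veteran", str(m.c), str(m.d), str(m.predicted_veteran)),
        ("Total", str(m.true_non_veteran), str(m.true_veteran), str(m.n)),
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    )


def report_as_dict(report: ValidationReport, ndigits: int | None = None) -> dict:
    """Report as a plain dict (for JSON); optional presentation rounding."""
    def fmt(v):
        if v is None or ndigits is None:
            return v
        return round(v, ndigits)

    return {
        "n": report.n,
        "convention": report.positive_class_convention,
        "agreement": fmt(report.agreement),
        "agreement_percent": fmt(100 * report.agreement),
        "ppv_veteran": fmt(report.ppv_veteran),
        "npv_veteran": fmt(report.npv_veteran),
        "sensitivity": fmt(report.sensitivity),
        "specificity": fmt(report.specificity),
        "sensitivity_study": fmt(report.sensitivity_study),
        "specificity_study": fmt(report.specificity_study),
        "sensitivity_std": fmt(report.sensitivity_std),
        "specificity_std": fmt(report.specificity_std),
        "youden_j": fmt(report.youden_j),
    }
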