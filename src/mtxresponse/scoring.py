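"""DAS28-CRP scoring and the windowed, dose-normalized response statistics.

The composite disease-activity score over 28 joints is

    DAS28 = 0.56*sqrt(T28) + 0.28*sqrt(S28) + 0.36*ln(CRP + 1)
            + 0.014*VAS + 0.96

with T28/S28 the tender/swollen joint counts (0-28), VAS the patient global
assessment on a 0-100 scale, and CRP the C-reactive protein concentration.
CRP is consumed in whatever unit the caller supplies; no conversion is
applied silently (declare the unit at the pipeline level).

From a patient's visit series the module derives, over an analysis window
``(t0, t1)`` in months:

* ``das28_auc`` — trapezoidal area under the piecewise-linear DAS28
  trajectory, with linear interpolation at window edges that fall between
  visits (score·months);
* ``improved_area`` — the reference area for a trajectory pinned at
  DAS28 = 10 (i.e. ``10 * (t1 - t0)``: 30 over 0-3 months, 60 over 0-6
  months) minus the actual area; larger means more improvement;
* ``cumulative_dose`` — weekly methotrexate dose summed over the window,
  using 4 weeks per month by default (``CALENDAR_WEEKS_PER_MONTH`` gives a
  calendar-exact alternative);
* ``index_r`` — improved area per milligram of cumulative dose (1/mg), the
  dose-normalized response statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CoverageError, ValidationError, ZeroDoseError

__all__ = [
    "Visit",
    "DoseInterval",
    "Patient",
    "ResponseSummary",
    "das28_crp",
    "das28_auc",
    "improved_area",
    "cumulative_dose",
    "index_r",
    "compute_response",
    "REFERENCE_DAS28",
    "WEEKS_PER_MONTH",
    "CALENDAR_WEEKS_PER_MONTH",
]

#: DAS28 level of the reference (no-improvement) trajectory.
REFERENCE_DAS28 = 10.0

#: Month-to-week conversion used for cumulative dose: 12 weekly doses in 3 months.
WEEKS_PER_MONTH = 4.0

#: Calendar-exact alternative (365.25 days/year / 12 months / 7 days).
CALENDAR_WEEKS_PER_MONTH = 365.25 / 12.0 / 7.0


def das28_crp(t28: float, s28: float, vas: float, crp: float) -> float:
    """DAS28-CRP from its four components.

    Parameters
    ----------
    t28, s28
        Tender / swollen joint counts out of 28 assessed joints.
    vas
        Patient global assessment, 0-100.
    crp
        C-reactive protein concentration (unit as supplied), >= 0.

    Returns
    -------
    float
        The composite score. Strictly increasing in every component.
    """
    if not 0 <= t28 <= 28:
        raise ValidationError(f"t28 must be in [0, 28], got {t28!r}")
    if not 0 <= s28 <= 28:
        raise ValidationError(f"s28 must be in [0, 28], got {s28!r}")
    if not 0 <= vas <= 100:
        raise ValidationError(f"vas must be in [0, 100], got {vas!r}")
    if not crp >= 0:
        raise ValidationError(f"crp must be >= 0, got {crp!r}")
    return (
        0.56 * math.sqrt(t28)
        + 0.28 * math.sqrt(s28)
        + 0.36 * math.log(crp + 1.0)
        + 0.014 * vas
        + 0.96
    )


@dataclass(frozen=True)
class Visit:
    """One clinic encounter: time since MTX start plus the DAS28 components.

    Either the four components or an explicit ``das28`` must be given. When
    components are present the score is always (re)computed from them; a
    ``das28`` passed alongside components must agree with the formula.
    """

    month: float
    t28: int | None = None
    s28: int | None = None
    vas: float | None = None
    crp: float | None = None
    das28: float | None = None

    def __post_init__(self) -> None:
        if not self.month >= 0:
            raise ValidationError(f"month must be >= 0, got {self.month!r}")
        components = (self.t28, self.s28, self.vas, self.crp)
        if all(c is not None for c in components):
            score = das28_crp(self.t28, self.s28, self.vas, self.crp)
            if self.das28 is not None and not math.isclose(
                self.das28, score, rel_tol=0, abs_tol=1e-6
            ):
                raise ValidationError(
                    f"das28={self.das28!r} inconsistent with components "
                    f"(formula gives {score:.6f}) at month {self.month}"
                )
            object.__setattr__(self, "das28", score)
        elif any(c is not None for c in components):
            missing = [
                name
                for name, c in zip(("t28", "s28", "vas", "crp"), components)
                if c is None
            ]
            raise ValidationError(
                f"visit at month {self.month} has partial components; "
                f"missing {missing}"
            )
        elif self.das28 is None:
            raise ValidationError(
                f"visit at month {self.month} needs components or an "
                "explicit das28 score"
            )
        elif self.das28 < 0:
            raise ValidationError(f"das28 must be >= 0, got {self.das28!r}")


@dataclass(frozen=True)
class DoseInterval:
    """Constant weekly MTX dose over the half-open interval [start, end) months."""

    start_month: float
    end_month: float
    weekly_dose_mg: float

    def __post_init__(self) -> None:
        if not self.start_month < self.end_month:
            raise ValidationError(
                f"dose interval needs start_month < end_month, got "
                f"[{self.start_month}, {self.end_month})"
            )
        if not self.weekly_dose_mg >= 0:
            raise ValidationError(
                f"weekly_dose_mg must be >= 0, got {self.weekly_dose_mg!r}"
            )


@dataclass
class Patient:
    """Visits, dose schedule and genotype calls for one study participant."""

    patient_id: str
    visits: Sequence[Visit]
    doses: Sequence[DoseInterval] = field(default_factory=list)
    genotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValidationError(f"patient {self.patient_id}: no visits")
        months = [v.month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: visits must be strictly "
                f"time-sorted, got months {months}"
            )
        if months[0] != 0:
            raise ValidationError(
                f"patient {self.patient_id}: first visit must be at month 0, "
                f"got {months[0]}"
            )
        starts = sorted(self.doses, key=lambda d: d.start_month)
        for a, b in zip(starts, starts[1:]):
            if b.start_month < a.end_month:
                raise ValidationError(
                    f"patient {self.patient_id}: overlapping dose intervals "
                    f"[{a.start_month},{a.end_month}) and "
                    f"[{b.start_month},{b.end_month})"
                )


@dataclass(frozen=True)
class ResponseSummary:
    """Per-patient response quantities over one analysis window."""

    patient_id: str
    window: tuple[float, float]
    cumulative_dose_mg: float
    das28_auc: float
    improved_area: float
    index_r: float


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    t0, t1 = window
    if not (t0 >= 0 and t0 < t1):
        raise ValidationError(f"window must satisfy 0 <= t0 < t1, got {window!r}")
    return float(t0), float(t1)


def _trajectory(visits: Sequence[Visit]) -> tuple[np.ndarray, np.ndarray]:
    months = np.asarray([v.month for v in visits], dtype=float)
    scores = np.asarray([v.das28 for v in visits], dtype=float)
    if months.size < 2:
        raise CoverageError("at least two visits are needed to form a trajectory")
    if np.any(np.diff(months) <= 0):
        raise ValidationError("visit months must be strictly increasing")
    return months, scores


def das28_auc(visits: Sequence[Visit], window: tuple[float, float]) -> float:
    """Trapezoidal area under the piecewise-linear DAS28 trajectory.

    The trajectory is the linear interpolant through the visit scores; if a
    window edge falls between visits its value is interpolated from the
    bracketing visits. Visits must bracket the whole window — the trajectory
    is never extrapolated.
    """
    t0, t1 = _check_window(window)
    months, scores = _trajectory(visits)
    if months[0] > t0 or months[-1] < t1:
        raise CoverageError(
            f"visits span [{months[0]}, {months[-1]}] months and do not "
            f"cover the window ({t0}, {t1})"
        )
    interior = months[(months > t0) & (months < t1)]
    grid = np.concatenate(([t0], interior, [t1]))
    values = np.interp(grid, months, scores)
    return float(np.trapezoid(values, grid))


def improved_area(
    visits: Sequence[Visit],
    window: tuple[float, float],
    reference_das28: float = REFERENCE_DAS28,
) -> float:
    """Reference area minus the actual DAS28 area over the window.

    The reference assumes DAS28 pinned at ``reference_das28`` (default 10)
    throughout, i.e. an area of 30 over 0-3 months and 60 over 0-6 months.
    A negative result (trajectory above the reference) is reported with a
    warning, not clipped.
    """
    t0, t1 = _check_window(window)
    area = reference_das28 * (t1 - t0) - das28_auc(visits, window)
    if area < 0:
        warnings.warn(
            f"improved area is negative ({area:.3f}) over window ({t0}, {t1}); "
            "the trajectory exceeds the reference level",
            stacklevel=2,
        )
    return area


def cumulative_dose(
    doses: Sequence[DoseInterval],
    window: tuple[float, float],
    weeks_per_month: float = WEEKS_PER_MONTH,
) -> float:
    """Total MTX dose (mg) received during the window.

    Each interval contributes ``weekly_dose_mg * weeks of overlap``; months
    are converted to weeks at ``weeks_per_month`` (4 by default, so a
    3-month window holds exactly 12 weekly doses). The intervals must cover
    the window without gaps.
    """
    t0, t1 = _check_window(window)
    ordered = sorted(doses, key=lambda d: d.start_month)
    total = 0.0
    covered = 0.0
    for iv in ordered:
        overlap = min(iv.end_month, t1) - max(iv.start_month, t0)
        if overlap > 0:
            total += iv.weekly_dose_mg * overlap * weeks_per_month
            covered += overlap
    if not math.isclose(covered, t1 - t0, rel_tol=0, abs_tol=1e-9):
        raise CoverageError(
            f"dose intervals cover {covered:g} of the {t1 - t0:g} months in "
            f"window ({t0}, {t1})"
        )
    return total


def index_r(
    visits: Sequence[Visit],
    doses: Sequence[DoseInterval],
    window: tuple[float, float],
    weeks_per_month: float = WEEKS_PER_MONTH,
    patient_id: str = "",
) -> ResponseSummary:
    """Dose-normalized response: improved area per mg of cumulative MTX.

    Returns a :class:`ResponseSummary` carrying every intermediate quantity
    (cumulative dose, actual area, improved area) alongside the index.
    """
    dose = cumulative_dose(doses, window, weeks_per_month)
    if dose <= 0:
        raise ZeroDoseError(
            f"cumulative dose over window {window!r} is {dose:g} mg; "
            "index R is undefined"
        )
    auc = das28_auc(visits, window)
    t0, t1 = _check_window(window)
    area = REFERENCE_DAS28 * (t1 - t0) - auc
    if area < 0:
        warnings.warn(
            f"improved area is negative ({area:.3f}) over window ({t0}, {t1})",
            stacklevel=2,
        )
    return ResponseSummary(
        patient_id=patient_id,
        window=(t0, t1),
        cumulative_dose_mg=dose,
        das28_auc=auc,
        improved_area=area,
        index_r=area / dose,
    )


def compute_response(
    patient: Patient,
    window: tuple[float, float],
    weeks_per_month: float = WEEKS_PER_MONTH,
) -> ResponseSummary:
    """Convenience wrapper: :func:`index_r` on a :class:`Patient`."""
    return index_r(
        patient.visits,
        patient.doses,
        window,
        weeks_per_month=weeks_per_month,
        patient_id=patient.patient_id,
    )
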