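"""Synthetic RA cohorts with the structure the analysis assumes.

The generator emulates a small observational methotrexate cohort: 21
patients (7 destined for good disease control, 14 for poor), monthly
visits over the first year of treatment, DAS28-CRP trajectories that
decline linearly from a baseline near 4.0 at a group-specific rate
(floored at zero), and piecewise-constant weekly dose schedules whose
3-month cumulative doses land in the 72-120 mg range typical of low-dose
Japanese regimens.

DAS28 values are never injected directly. Each visit's target score
(trajectory value plus Gaussian measurement noise) is back-filled into
components: VAS and CRP come from auxiliary models tied to the target
(with jitter scaled by the same noise parameter), the joint-count terms
absorb the remainder, counts are rounded to integers in [0, 28], and the
ground-truth DAS28 is then *recomputed from the rounded components* — the
scoring formula stays the single source of truth. Rounding makes the
realized trajectory deviate from the target by up to a few tenths of a
DAS28 unit, which acts as a small extra discretization noise.

Genotypes are sampled per SNP at the binary carrier-group level with the
frequencies observed in the emulated study (e.g. 15/21 RFC1 80 A-allele
carriers), then rendered as a concrete diploid call uniformly from the
group's genotype strings. An optional multiplicative genotype effect on
the response (applied to the decline rate of carriers) lets power and
type-I-error experiments switch a true association on or off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .classification import SNP_GROUPINGS, SNP_ORDER
from .errors import ValidationError
from .io import write_patients
from .scoring import DoseInterval, Patient, Visit

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_CARRIER_PROBABILITIES",
]

#: Fraction of patients in each SNP's comparison (second) group, matching
#: the emulated study's margins out of 21 patients.
DEFAULT_CARRIER_PROBABILITIES: dict[str, float] = {
    "RFC1_80": 15 / 21,    # A-allele carriers
    "FPGS_1994": 4 / 21,   # A/A homozygotes
    "GGH_401": 10 / 21,    # T-allele carriers
    "MTHFR_1298": 2 / 21,  # C/C homozygotes
    "TYMS_UTR": 13 / 21,   # +6-allele carriers
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the generator.

    Defaults encode the emulated cohort: n = 21 with 7 good responders,
    monthly visits over months 0-12, baseline DAS28 centred on 4.0, and
    weekly dose levels of 6-10 mg chosen once per patient. Decline rates
    are in DAS28 units per month; the good-group default (0.5) brings a
    median baseline under the control threshold of 2 by month 6, while the
    poor-group default (0.15) leaves it above through month 12.
    """

    n_patients: int = 21
    n_good: int = 7
    visit_times: tuple[float, ...] = tuple(float(m) for m in range(13))
    baseline_das28_mean: float = 4.0
    baseline_das28_sd: float = 1.0
    good_decline_rate: float = 0.5
    poor_decline_rate: float = 0.15
    measurement_noise_sd: float = 0.25
    weekly_dose_levels: tuple[float, ...] = (6.0, 8.0, 10.0)
    dose_change_probability: float = 0.5  # poor patients only
    genotype_group_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_PROBABILITIES)
    )
    genotype_effect_on_R: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_good < self.n_patients:
            raise ValidationError(
                f"n_good must satisfy 0 < n_good < n_patients, got "
                f"n_good={self.n_good}, n_patients={self.n_patients}"
            )
        times = self.visit_times
        if not times or times[0] != 0:
            raise ValidationError(
                f"visit_times must start at exactly 0, got {times!r}"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"visit_times must be sorted, got {times!r}")
        for name in ("good_decline_rate", "poor_decline_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.measurement_noise_sd < 0:
            raise ValidationError(
                f"measurement_noise_sd must be >= 0, got {self.measurement_noise_sd!r}"
            )
        if self.baseline_das28_sd < 0:
            raise ValidationError(
                f"baseline_das28_sd must be >= 0, got {self.baseline_das28_sd!r}"
            )
        if not self.weekly_dose_levels or any(d <= 0 for d in self.weekly_dose_levels):
            raise ValidationError(
                f"weekly_dose_levels must be positive, got {self.weekly_dose_levels!r}"
            )
        if not 0 <= self.dose_change_probability <= 1:
            raise ValidationError(
                "dose_change_probability must be in [0, 1], got "
                f"{self.dose_change_probability!r}"
            )
        for snp, prob in self.genotype_group_probabilities.items():
            if snp not in SNP_GROUPINGS:
                raise ValidationError(
                    f"genotype_group_probabilities: unknown SNP {snp!r}"
                )
            if not 0 <= prob <= 1:
                raise ValidationError(
                    f"genotype_group_probabilities[{snp!r}] must be in [0, 1], "
                    f"got {prob!r}"
                )
        if self.genotype_effect_on_R is not None:
            for snp, eff in self.genotype_effect_on_R.items():
                if snp not in SNP_GROUPINGS:
                    raise ValidationError(f"genotype_effect_on_R: unknown SNP {snp!r}")
                if eff <= 0:
                    raise ValidationError(
                        f"genotype_effect_on_R[{snp!r}] must be > 0, got {eff!r}"
                    )


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth and the config that made it."""

    patients: list[Patient]
    true_labels: dict[str, str]  # patient_id -> "good" | "poor"
    config_echo: CohortConfig

    def __post_init__(self) -> None:
        if len(self.true_labels) != len(self.patients):
            raise ValidationError("one true label per patient is required")


def _components_for_target(
    target: float, vas_jitter: float, crp_log_jitter: float
) -> tuple[int, int, float, float]:
    """Back-fill DAS28 components for a target score.

    VAS tracks the target on a 10x scale and CRP follows an exponential
    link calibrated so a baseline score of 4 yields CRP near 1.2 mg/dL;
    the joint-count terms absorb whatever remains, with tender and swollen
    counts kept equal before rounding.
    """
    d = max(float(target), 0.0)
    vas = float(np.clip(round(10.0 * d + vas_jitter), 0, 100))
    crp = max(math.exp(0.2 * d + crp_log_jitter) - 1.0, 0.0)
    remainder = d - 0.36 * math.log(crp + 1.0) - 0.014 * vas - 0.96
    if remainder < 0:
        # Target below what the chosen VAS/CRP allow: drop to the minimal
        # deterministic configuration that still matches the target.
        vas = 0.0
        crp = max(math.exp(max(d - 0.96, 0.0) / 0.36) - 1.0, 0.0)
        t28 = s28 = 0
    else:
        count = int(np.clip(round((remainder / 0.84) ** 2), 0, 28))
        t28 = s28 = count
    crp = round(crp, 4)
    return t28, s28, vas, crp


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``config.seed``."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    statuses = np.array(
        ["good"] * config.n_good + ["poor"] * (n - config.n_good)
    )
    statuses = rng.permutation(statuses)
    months = np.asarray(config.visit_times, dtype=float)
    effects = dict(config.genotype_effect_on_R or {})

    patients: list[Patient] = []
    true_labels: dict[str, str] = {}
    width = max(2, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        status = str(statuses[i])

        # genotype calls, sampled at the carrier-group level
        genotypes: dict[str, str] = {}
        in_comparison: dict[str, bool] = {}
        for snp in SNP_ORDER:
            grouping = SNP_GROUPINGS[snp]
            prob = config.genotype_group_probabilities.get(snp, 0.5)
            comparison = bool(rng.random() < prob)
            in_comparison[snp] = comparison
            pool = sorted(
                grouping.comparison_genotypes if comparison
                else grouping.reference_genotypes
            )
            genotypes[snp] = pool[int(rng.integers(len(pool)))]

        # dose schedule: one weekly level; poor patients may get a bump
        # inside the control window (the dose instability that marks them)
        level = float(
            config.weekly_dose_levels[int(rng.integers(len(config.weekly_dose_levels)))]
        )
        change = status == "poor" and rng.random() < config.dose_change_probability
        change_month = float(rng.integers(7, 11))  # used only if change
        horizon = max(12.0, months[-1])
        if change:
            doses = [
                DoseInterval(0.0, change_month, level),
                DoseInterval(change_month, horizon, level + 2.0),
            ]
        else:
            doses = [DoseInterval(0.0, horizon, level)]

        # DAS28 trajectory: linear decline, floored at zero, plus noise
        baseline = float(
            np.clip(
                rng.normal(config.baseline_das28_mean, config.baseline_das28_sd),
                1.0,
                9.0,
            )
        )
        rate = (
            config.good_decline_rate if status == "good" else config.poor_decline_rate
        )
        for snp, carrier in in_comparison.items():
            if carrier and snp in effects:
                rate *= effects[snp]
        targets = np.maximum(baseline - rate * months, 0.0)
        noise = rng.normal(0.0, config.measurement_noise_sd, size=months.size)
        vas_jitter = rng.normal(0.0, 30.0 * config.measurement_noise_sd, size=months.size)
        crp_jitter = rng.normal(0.0, 0.5 * config.measurement_noise_sd, size=months.size)
        visits = []
        for j, month in enumerate(months):
            t28, s28, vas, crp = _components_for_target(
                targets[j] + noise[j], vas_jitter[j], crp_jitter[j]
            )
            visits.append(Visit(month=month, t28=t28, s28=s28, vas=vas, crp=crp))

        patients.append(
            Patient(patient_id=pid, visits=visits, doses=doses, genotypes=genotypes)
        )
        true_labels[pid] = status

    return SyntheticCohort(
        patients=patients, true_labels=true_labels, config_echo=config
    )


def write_cohort(cohort: SyntheticCohort, destination: str | Path) -> dict[str, Path]:
    """Emit visits.csv, doses.csv and genotypes.csv for a cohort.

    The files use exactly the dialect :func:`mtxresponse.io.read_patients`
    consumes, and the round trip preserves all numeric content.
    """
    return write_patients(cohort.patients, destination)
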