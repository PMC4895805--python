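"""End-to-end orchestration: cohort in, report bundle out.

A run either simulates a cohort or ingests the three CSV inputs, then:

1. scores every patient over the analysis windows (0-3 and 0-6 months):
   cumulative dose, DAS28 AUC, improved area, index R;
2. labels disease control over months 6-12;
3. maps genotype calls to the five binary comparison groups;
4. builds the good-vs-poor comparisons (3 variables x 2 windows) and the
   per-SNP index-R comparisons;
5. writes everything, plus a reproducibility manifest recording every
   convention in force (quartile rule, weeks-per-month factor, control
   rule mode, test sidedness, exact-test cap, CRP unit).

Patients that fail a precondition — no baseline visit, a window not
covered by visits or doses, no visits in the control window — are
excluded from the affected analysis only, with the reason logged; nothing
is imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classification import (
    SNP_ORDER,
    ControlCriteria,
    classify_control,
    group_genotype,
)
from .errors import IndeterminateControlError, MtxResponseError, ValidationError
from .io import read_patients
from .scoring import (
    WEEKS_PER_MONTH,
    Patient,
    compute_response,
)
from .stats import QUARTILE_RULE, build_table2, build_table3
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

__all__ = ["RunConfig", "RunResult", "run"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on, in one place."""

    mode: str = "simulate"  # "simulate" | "csv"
    cohort: CohortConfig | None = None
    visits_csv: str | Path | None = None
    doses_csv: str | Path | None = None
    genotypes_csv: str | Path | None = None
    criteria: ControlCriteria = field(default_factory=ControlCriteria)
    windows: tuple[tuple[float, float], ...] = ((0.0, 3.0), (0.0, 6.0))
    stats_method: str = "auto"
    exact_cap: int = 25
    weeks_per_month: float = WEEKS_PER_MONTH
    crp_unit: str = "mg/dL"
    out_dir: str | Path = "mtxresponse_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "csv"):
            raise ValidationError(f"mode must be 'simulate' or 'csv', got {self.mode!r}")
        if self.mode == "csv":
            missing = [
                name
                for name in ("visits_csv", "doses_csv", "genotypes_csv")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValidationError(f"csv mode requires paths for {missing}")


@dataclass
class RunResult:
    """In-memory view of a completed run plus where it was written."""

    out_dir: Path
    summaries: pd.DataFrame
    labels: pd.DataFrame
    groups: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    manifest: dict
    exclusions: list[dict]
    true_labels: dict[str, str] | None = None


def _load_patients(
    config: RunConfig,
) -> tuple[list[Patient], SyntheticCohort | None, list[tuple[str, str]]]:
    if config.mode == "simulate":
        cohort_config = config.cohort or CohortConfig(seed=config.seed)
        if cohort_config.seed != config.seed:
            cohort_config = CohortConfig(
                **{**cohort_config.__dict__, "seed": config.seed}
            )
        cohort = generate_cohort(cohort_config)
        return list(cohort.patients), cohort, []
    patients, skipped = read_patients(
        config.visits_csv, config.doses_csv, config.genotypes_csv, invalid="skip"
    )
    return patients, None, skipped


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, cohort, skipped = _load_patients(config)
    if cohort is not None:
        write_cohort(cohort, out / "inputs")

    exclusions: list[dict] = []
    for pid, reason in skipped:
        exclusions.append(dict(patient_id=pid, stage="input", reason=reason))
        logger.warning("patient %s excluded at input: %s", pid, reason)

    # 1. response summaries per window
    summary_rows = []
    summaries = []
    for window in config.windows:
        for p in patients:
            try:
                s = compute_response(p, window, weeks_per_month=config.weeks_per_month)
            except MtxResponseError as exc:
                exclusions.append(
                    dict(patient_id=p.patient_id, stage=f"response {window}", reason=str(exc))
                )
                logger.warning(
                    "patient %s excluded from window %s: %s", p.patient_id, window, exc
                )
                continue
            summaries.append(s)
            summary_rows.append(
                dict(
                    patient_id=s.patient_id,
                    window=f"{window[0]:g}-{window[1]:g}",
                    cumulative_dose_mg=s.cumulative_dose_mg,
                    das28_auc=s.das28_auc,
                    improved_area=s.improved_area,
                    index_r=s.index_r,
                )
            )
    summaries_df = pd.DataFrame(summary_rows)

    # 2. disease-control labels
    label_rows = []
    labels: dict[str, str] = {}
    for p in patients:
        try:
            lab = classify_control(p, config.criteria)
        except IndeterminateControlError as exc:
            exclusions.append(
                dict(patient_id=p.patient_id, stage="control label", reason=str(exc))
            )
            logger.warning("patient %s not labelled: %s", p.patient_id, exc)
            continue
        labels[p.patient_id] = lab.status
        label_rows.append(
            dict(
                patient_id=lab.patient_id,
                control_status=lab.status,
                reasons="; ".join(lab.reasons),
                n_window_visits=lab.n_window_visits,
                n_exceedances=lab.n_exceedances,
            )
        )
    labels_df = pd.DataFrame(label_rows)

    # 3. genotype groups
    group_rows = []
    genotype_groups: dict[str, dict[str, str]] = {}
    for p in patients:
        groups = {}
        for snp in SNP_ORDER:
            call = p.genotypes.get(snp)
            if call is None:
                continue
            groups[snp] = group_genotype(snp, call)
            group_rows.append(dict(patient_id=p.patient_id, snp=snp, group=groups[snp]))
        genotype_groups[p.patient_id] = groups
    groups_df = pd.DataFrame(group_rows)

    # 4. comparison tables, restricted to patients with a label and a
    #    summary in every analysis window (per-analysis exclusion, no
    #    imputation)
    ids_per_window = [
        {s.patient_id for s in summaries if tuple(s.window) == tuple(w)}
        for w in config.windows
    ]
    complete = set(labels).intersection(*ids_per_window) if ids_per_window else set()
    dropped = sorted(
        {p.patient_id for p in patients} - complete
    )
    for pid in dropped:
        if not any(e["patient_id"] == pid for e in exclusions):
            exclusions.append(
                dict(patient_id=pid, stage="comparison tables",
                     reason="missing label or window summary")
            )
    table2 = build_table2(
        [s for s in summaries if s.patient_id in complete],
        {pid: labels[pid] for pid in complete},
        method=config.stats_method,
        exact_cap=config.exact_cap,
        windows=config.windows,
    )
    ids_06 = {s.patient_id for s in summaries if tuple(s.window) == (0.0, 6.0)}
    table3 = build_table3(
        [s for s in summaries if tuple(s.window) == (0.0, 6.0)],
        {pid: g for pid, g in genotype_groups.items() if pid in ids_06},
        method=config.stats_method,
        exact_cap=config.exact_cap,
    )

    # 5. manifest + outputs
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_patients": len(patients),
        "windows": [list(w) for w in config.windows],
        "conventions": {
            "quartile_rule": QUARTILE_RULE,
            "weeks_per_month": config.weeks_per_month,
            "control_rule": config.criteria.mode,
            "control_window": list(config.criteria.window),
            "das28_threshold": config.criteria.das28_threshold,
            "sidedness": "two-sided",
            "stats_method": config.stats_method,
            "exact_cap": config.exact_cap,
            "tie_handling": "mid-ranks; exact permutation handles ties natively",
            "crp_unit": config.crp_unit,
            "reference_das28": 10.0,
        },
        "cohort_config": (
            {
                k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
                for k, v in (cohort.config_echo.__dict__.items() if cohort else [])
            }
            if cohort
            else None
        ),
        "exclusions": exclusions,
    }

    summaries_df.to_csv(out / "summaries.csv", index=False)
    labels_df.to_csv(out / "labels.csv", index=False)
    groups_df.to_csv(out / "groups.csv", index=False)
    table2.to_csv(out / "table2.csv", index=False)
    table3.to_csv(out / "table3.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        out_dir=out,
        summaries=summaries_df,
        labels=labels_df,
        groups=groups_df,
        table2=table2,
        table3=table3,
        manifest=manifest,
        exclusions=exclusions,
        true_labels=dict(cohort.true_labels) if cohort else None,
    )
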