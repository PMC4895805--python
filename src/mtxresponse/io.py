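"""CSV dialects for the three pipeline inputs.

visits.csv     patient_id, month, t28, s28, vas, crp
doses.csv      patient_id, start_month, end_month, weekly_dose_mg
genotypes.csv  patient_id, rfc1_80, fpgs_1994, ggh_401, mthfr_1298, tyms_utr

Genotypes are diploid strings such as ``G/A`` or ``-6/+6``. Floats are
written with Python's shortest round-trip representation, so a write/read
cycle preserves every numeric value exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .classification import SNP_ORDER, canonical_snp_name
from .errors import ValidationError
from .scoring import DoseInterval, Patient, Visit

__all__ = [
    "VISIT_COLUMNS",
    "DOSE_COLUMNS",
    "GENOTYPE_COLUMNS",
    "patients_to_frames",
    "write_patients",
    "read_patients",
]

VISIT_COLUMNS = ("patient_id", "month", "t28", "s28", "vas", "crp")
DOSE_COLUMNS = ("patient_id", "start_month", "end_month", "weekly_dose_mg")
GENOTYPE_COLUMNS = ("patient_id",) + tuple(s.lower() for s in SNP_ORDER)


def patients_to_frames(
    patients: Sequence[Patient],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Explode a patient list into the visits / doses / genotypes tables."""
    visit_rows, dose_rows, geno_rows = [], [], []
    for p in patients:
        for v in p.visits:
            if v.t28 is None:
                raise ValidationError(
                    f"patient {p.patient_id}: visit at month {v.month} has no "
                    "components; only component-level visits can be serialized"
                )
            visit_rows.append(
                dict(patient_id=p.patient_id, month=v.month, t28=v.t28,
                     s28=v.s28, vas=v.vas, crp=v.crp)
            )
        for d in p.doses:
            dose_rows.append(
                dict(patient_id=p.patient_id, start_month=d.start_month,
                     end_month=d.end_month, weekly_dose_mg=d.weekly_dose_mg)
            )
        row: dict[str, object] = {"patient_id": p.patient_id}
        for snp in SNP_ORDER:
            row[snp.lower()] = p.genotypes.get(snp, "")
        geno_rows.append(row)
    return (
        pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS)),
        pd.DataFrame(dose_rows, columns=list(DOSE_COLUMNS)),
        pd.DataFrame(geno_rows, columns=list(GENOTYPE_COLUMNS)),
    )


def write_patients(patients: Sequence[Patient], destination: str | Path) -> dict[str, Path]:
    """Write the three input CSVs under ``destination`` (created if needed)."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    visits, doses, genotypes = patients_to_frames(patients)
    paths = {
        "visits": dest / "visits.csv",
        "doses": dest / "doses.csv",
        "genotypes": dest / "genotypes.csv",
    }
    visits.to_csv(paths["visits"], index=False)
    doses.to_csv(paths["doses"], index=False)
    genotypes.to_csv(paths["genotypes"], index=False)
    return paths


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_patients(
    visits_csv: str | Path,
    doses_csv: str | Path,
    genotypes_csv: str | Path,
    invalid: str = "raise",
) -> list[Patient] | tuple[list[Patient], list[tuple[str, str]]]:
    """Assemble patients from the three CSV inputs.

    Rows that cannot be parsed raise with the file, row number and column
    spelled out. A structurally invalid patient (e.g. no baseline visit)
    raises by default; with ``invalid="skip"`` such patients are dropped
    and the return value becomes ``(patients, [(patient_id, reason), ...])``.
    Patients are returned in order of first appearance in the visits table.
    """
    if invalid not in ("raise", "skip"):
        raise ValidationError(f"invalid must be 'raise' or 'skip', got {invalid!r}")
    visits = pd.read_csv(visits_csv)
    doses = pd.read_csv(doses_csv)
    genotypes = pd.read_csv(genotypes_csv, dtype=str)
    _require_columns(visits, VISIT_COLUMNS, visits_csv)
    _require_columns(doses, DOSE_COLUMNS, doses_csv)
    _require_columns(genotypes, GENOTYPE_COLUMNS, genotypes_csv)

    patients: list[Patient] = []
    skipped: list[tuple[str, str]] = []
    dose_groups = dict(tuple(doses.groupby("patient_id", sort=False)))
    geno_rows = genotypes.set_index("patient_id")
    for pid, group in visits.groupby("patient_id", sort=False):
        visit_list = []
        for idx, row in group.sort_values("month").iterrows():
            try:
                visit_list.append(
                    Visit(
                        month=float(row["month"]),
                        t28=int(row["t28"]),
                        s28=int(row["s28"]),
                        vas=float(row["vas"]),
                        crp=float(row["crp"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{visits_csv}: row {idx + 2} (patient {pid}): {exc}"
                ) from exc
        dose_list = []
        for idx, row in dose_groups.get(pid, pd.DataFrame(columns=DOSE_COLUMNS)).iterrows():
            try:
                dose_list.append(
                    DoseInterval(
                        start_month=float(row["start_month"]),
                        end_month=float(row["end_month"]),
                        weekly_dose_mg=float(row["weekly_dose_mg"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{doses_csv}: row {idx + 2} (patient {pid}): {exc}"
                ) from exc
        geno: dict[str, str] = {}
        if pid in geno_rows.index:
            for snp in SNP_ORDER:
                value = geno_rows.at[pid, snp.lower()]
                if isinstance(value, str) and value:
                    geno[canonical_snp_name(snp)] = value
        try:
            patients.append(
                Patient(patient_id=str(pid), visits=visit_list, doses=dose_list,
                        genotypes=geno)
            )
        except ValidationError as exc:
            if invalid == "skip":
                skipped.append((str(pid), str(exc)))
            else:
                raise
    if invalid == "skip":
        return patients, skipped
    return patients
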