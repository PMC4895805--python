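"""Disease-control labelling and folate-pathway genotype grouping.

Disease control over months 6-12 is "good" when the weekly MTX dose stayed
fixed throughout the window and DAS28 exceeded the threshold (default 2.0)
at fewer visits than the allowed budget; everything else is "poor". The
"less than once per month" reading gives a budget of one exceedance per
month of window (strictly fewer than 6 over a 6-month window); a stricter
reading — DAS28 never above the threshold — is available via
``strict_mode``. Both are implemented because the two phrasings circulate
in the clinical literature; the mode in force is recorded in pipeline
output.

The five SNPs are each collapsed to a binary contrast, homozygous-reference
versus variant-allele carrier (or the reverse, matching the contrast the
analysis uses):

========== ======================= =====================
SNP        reference group         comparison group
========== ======================= =====================
RFC1 80G>A        G/G              A allele (G/A, A/A)
FPGS 1994G>A      G allele         A/A
GGH -401C>T       C/C              T allele (C/T, T/T)
MTHFR 1298A>C     A allele         C/C
TYMS 3'-UTR       -6/-6            +6 allele
========== ======================= =====================

GGH -401C>T (rs3758149) is sometimes labelled "GGH 452" in report tables;
both names are accepted here and map to the same SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import (
    GenotypeParseError,
    IndeterminateControlError,
    ValidationError,
)
from .scoring import Patient

__all__ = [
    "ControlCriteria",
    "ControlLabel",
    "GenotypeGrouping",
    "SNP_GROUPINGS",
    "SNP_ORDER",
    "classify_control",
    "group_genotype",
    "normalize_genotype",
    "canonical_snp_name",
]


@dataclass(frozen=True)
class ControlCriteria:
    """Rule defining good vs poor disease control.

    ``max_exceedances_per_month`` expresses the "less than once per month"
    budget: good control allows strictly fewer than
    ``rate * window length`` visits with DAS28 above the threshold. With
    ``strict_mode`` no exceedance at all is tolerated.
    """

    window: tuple[float, float] = (6.0, 12.0)
    das28_threshold: float = 2.0
    max_exceedances_per_month: float = 1.0
    require_fixed_dose: bool = True
    strict_mode: bool = False

    def __post_init__(self) -> None:
        if not self.das28_threshold > 0:
            raise ValidationError(
                f"das28_threshold must be > 0, got {self.das28_threshold!r}"
            )
        if not self.window[0] < self.window[1]:
            raise ValidationError(f"window start must precede end, got {self.window!r}")
        if not self.max_exceedances_per_month >= 0:
            raise ValidationError(
                "max_exceedances_per_month must be >= 0, got "
                f"{self.max_exceedances_per_month!r}"
            )

    @property
    def mode(self) -> str:
        return "strict" if self.strict_mode else "default"


@dataclass(frozen=True)
class ControlLabel:
    """A good/poor label together with the reasons for a poor call."""

    patient_id: str
    status: str  # "good" | "poor"
    reasons: tuple[str, ...] = ()
    n_window_visits: int = 0
    n_exceedances: int = 0


def classify_control(patient: Patient, criteria: ControlCriteria | None = None) -> ControlLabel:
    """Label a patient's disease control over the criteria window.

    Good requires (when ``require_fixed_dose``) a single weekly dose level
    across every dose interval intersecting the window, and an exceedance
    count below the budget. A patient with no visits in the window cannot
    be labelled and raises :class:`IndeterminateControlError` rather than
    receiving a silent default.
    """
    criteria = criteria or ControlCriteria()
    t0, t1 = criteria.window
    in_window = [v for v in patient.visits if t0 <= v.month <= t1]
    if not in_window:
        raise IndeterminateControlError(
            f"patient {patient.patient_id}: no visits in control window ({t0}, {t1})"
        )
    reasons: list[str] = []

    if criteria.require_fixed_dose:
        levels = {
            iv.weekly_dose_mg
            for iv in patient.doses
            if min(iv.end_month, t1) - max(iv.start_month, t0) > 0
        }
        if len(levels) > 1:
            reasons.append(
                "dose change during control window "
                f"(weekly doses {sorted(levels)} mg)"
            )

    exceedances = sum(1 for v in in_window if v.das28 > criteria.das28_threshold)
    if criteria.strict_mode:
        allowed = 0
        ok = exceedances == 0
    else:
        allowed = criteria.max_exceedances_per_month * (t1 - t0)
        ok = exceedances < allowed
    if not ok:
        reasons.append(
            f"DAS28 > {criteria.das28_threshold:g} at {exceedances} of "
            f"{len(in_window)} window visits (budget: "
            f"{'0' if criteria.strict_mode else f'< {allowed:g}'})"
        )

    return ControlLabel(
        patient_id=patient.patient_id,
        status="good" if not reasons else "poor",
        reasons=tuple(reasons),
        n_window_visits=len(in_window),
        n_exceedances=exceedances,
    )


@dataclass(frozen=True)
class GenotypeGrouping:
    """Binary carrier contrast for one SNP.

    ``alleles`` fixes the canonical allele order used to normalize calls
    (so "A/G" and "G/A" are the same heterozygote). ``reference_genotypes``
    and ``comparison_genotypes`` partition the three possible genotypes.
    """

    snp_name: str
    alleles: tuple[str, str]
    reference_group_label: str
    comparison_group_label: str
    reference_genotypes: frozenset[str]
    comparison_genotypes: frozenset[str]
    aliases: tuple[str, ...] = ()

    def group(self, genotype: str) -> str:
        call = normalize_genotype(self, genotype)
        if call in self.reference_genotypes:
            return self.reference_group_label
        return self.comparison_group_label


def _grouping(
    snp: str,
    alleles: tuple[str, str],
    ref_label: str,
    comp_label: str,
    ref_genotypes: set[str],
    aliases: tuple[str, ...] = (),
) -> GenotypeGrouping:
    a, b = alleles
    all_genotypes = {f"{a}/{a}", f"{a}/{b}", f"{b}/{b}"}
    return GenotypeGrouping(
        snp_name=snp,
        alleles=alleles,
        reference_group_label=ref_label,
        comparison_group_label=comp_label,
        reference_genotypes=frozenset(ref_genotypes),
        comparison_genotypes=frozenset(all_genotypes - ref_genotypes),
        aliases=aliases,
    )


#: Canonical SNP order used throughout reports.
SNP_ORDER = ("RFC1_80", "FPGS_1994", "GGH_401", "MTHFR_1298", "TYMS_UTR")

SNP_GROUPINGS: dict[str, GenotypeGrouping] = {
    "RFC1_80": _grouping(
        "RFC1_80", ("G", "A"), "G/G", "A allele", {"G/G"}
    ),
    "FPGS_1994": _grouping(
        "FPGS_1994", ("G", "A"), "G allele", "A/A", {"G/G", "G/A"}
    ),
    "GGH_401": _grouping(
        "GGH_401", ("C", "T"), "C/C", "T allele", {"C/C"}, aliases=("GGH_452",)
    ),
    "MTHFR_1298": _grouping(
        "MTHFR_1298", ("A", "C"), "A allele", "C/C", {"A/A", "A/C"}
    ),
    "TYMS_UTR": _grouping(
        "TYMS_UTR", ("-6", "+6"), "-6/-6", "+6 allele", {"-6/-6"}
    ),
}

_ALIASES = {
    alias: name
    for name, g in SNP_GROUPINGS.items()
    for alias in g.aliases
}


def canonical_snp_name(snp_name: str) -> str:
    """Resolve a SNP name (case/separator-insensitive, aliases allowed)."""
    key = snp_name.strip().upper().replace("-", "_").replace(" ", "_")
    key = _ALIASES.get(key, key)
    if key not in SNP_GROUPINGS:
        raise GenotypeParseError(
            f"unknown SNP {snp_name!r}; known: {', '.join(SNP_ORDER)}"
        )
    return key


def normalize_genotype(grouping: GenotypeGrouping, genotype: str) -> str:
    """Canonicalize a diploid call: unicode dashes to ASCII, allele order fixed."""
    raw = genotype.strip().replace("−", "-").replace("–", "-")
    parts = raw.split("/")
    if len(parts) != 2:
        raise GenotypeParseError(
            f"malformed genotype {genotype!r} for {grouping.snp_name}: "
            "expected two '/'-separated alleles"
        )
    order = {allele: i for i, allele in enumerate(grouping.alleles)}
    try:
        alleles = sorted((p.strip() for p in parts), key=lambda p: order[p])
    except KeyError:
        raise GenotypeParseError(
            f"genotype {genotype!r} has alleles outside "
            f"{grouping.alleles} for {grouping.snp_name}"
        ) from None
    return "/".join(alleles)


def group_genotype(snp_name: str, genotype: str) -> str:
    """Map a raw genotype call to its binary comparison-group label."""
    return SNP_GROUPINGS[canonical_snp_name(snp_name)].group(genotype)
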