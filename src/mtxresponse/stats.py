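"""Two-group nonparametric comparisons and quantile summaries.

The comparison statistic is the Mann-Whitney U. Small samples are tested
exactly: the null distribution of U is obtained by treating the pooled
observed values as fixed and considering every way of assigning them to
the two groups (a permutation test, which handles ties natively through
mid-ranks). For tie-free samples the null counts come from the classical
rank-sum subset recursion, which is equivalent to full enumeration but
costs O(n * n1 * W); tied samples are enumerated directly. Larger samples
fall back to the normal approximation with tie-corrected variance and
continuity correction (delegated to scipy).

Two-sided p-values throughout: an assignment is at least as extreme as the
observed one when |U - n1*n2/2| is at least the observed deviation. All
deviations are compared on the doubled-integer scale (mid-ranks step in
halves) so the exact path involves no floating-point tolerance.

Summaries follow the "median (25th-75th percentile)" convention with
linear interpolation between order statistics at position 1 + (n-1)*q.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import SNP_GROUPINGS, SNP_ORDER
from .errors import CohortJoinError, ValidationError
from .scoring import ResponseSummary

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "summarize",
    "build_table2",
    "build_table3",
    "QUARTILE_RULE",
]

#: Enumeration of tied samples is capped at this many assignments.
MAX_ENUMERATION = 2_000_000

#: Human-readable statement of the quantile convention (echoed in manifests).
QUARTILE_RULE = "linear interpolation between order statistics at 1 + (n-1)*q"


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group comparison, Table-style."""

    variable: str
    label_x: str
    label_y: str
    n_x: int
    n_y: int
    median_x: float
    q25_x: float
    q75_x: float
    median_y: float
    q25_y: float
    q75_y: float
    u_statistic: float
    p_value: float
    method: str  # "exact-permutation" | "normal-approx-tie-corrected"
    note: str = ""


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles of a non-empty sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    med, q25, q75 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q25), float(q75)


def _rank_sum_counts(n: int, n1: int) -> np.ndarray:
    """Counts of n1-subsets of ranks {1..n} by rank sum (subset-sum DP)."""
    max_w = n * (n + 1) // 2
    table = np.zeros((n1 + 1, max_w + 1))
    table[0, 0] = 1.0
    for k in range(1, n + 1):
        for j in range(min(k, n1), 0, -1):
            table[j, k:] += table[j - 1, : max_w + 1 - k]
    return table[n1]


def _exact_p_tie_free(u1: float, n1: int, n2: int) -> float:
    counts = _rank_sum_counts(n1 + n2, n1)
    offset = n1 * (n1 + 1) // 2
    u_values = np.arange(counts.size) - offset
    dev = np.abs(2 * u_values - n1 * n2)
    dev_obs = abs(int(round(2 * u1)) - n1 * n2)
    return float(counts[dev >= dev_obs].sum() / counts.sum())


def _exact_p_enumerate(ranks2: np.ndarray, u1: float, n1: int, n2: int) -> float:
    """Enumerate every assignment of the pooled values to group sizes (n1, n2).

    ``ranks2`` holds doubled mid-ranks (integers even with ties).
    """
    n = n1 + n2
    target = n1 * n2
    dev_obs = abs(int(round(2 * u1)) - target)
    shift = n1 * (n1 + 1)
    hits = 0
    total = comb(n, n1)
    if total > MAX_ENUMERATION:
        raise ValidationError(
            f"exact test with ties would enumerate {total} assignments "
            f"(cap {MAX_ENUMERATION}); use the normal approximation"
        )
    r = [int(v) for v in ranks2]
    for idx in itertools.combinations(range(n), n1):
        u2x = sum(r[i] for i in idx) - shift  # doubled U for this assignment
        if abs(u2x - target) >= dev_obs:
            hits += 1
    return hits / total


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_cap: int = 25,
    variable: str = "",
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Parameters
    ----------
    method
        ``"exact"`` forces the permutation null, ``"approx"`` forces the
        tie-corrected normal approximation, ``"auto"`` (default) uses the
        exact method whenever ``n1 + n2 <= exact_cap`` and, for tied
        samples, the enumeration stays below the internal cap.
    exact_cap
        Largest pooled sample size tested exactly under ``"auto"``.

    Returns
    -------
    GroupComparison
        U is the statistic of the first sample; ``U_x + U_y = n1*n2``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValidationError(
            f"both groups must be non-empty (n_x={xa.size}, n_y={ya.size})"
        )
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size
    note = ""

    degenerate = np.all(pooled == pooled[0])
    if degenerate:
        p = 1.0
        used = "exact-permutation"
        note = "all values identical across both groups; p = 1 by convention"
    else:
        use_exact = method == "exact" or (
            method == "auto"
            and n1 + n2 <= exact_cap
            and (not has_ties or comb(n1 + n2, n1) <= MAX_ENUMERATION)
        )
        if use_exact:
            if has_ties:
                ranks2 = np.rint(2 * ranks).astype(int)
                p = _exact_p_enumerate(ranks2, u1, n1, n2)
            else:
                p = _exact_p_tie_free(u1, n1, n2)
            used = "exact-permutation"
        else:
            res = sps.mannwhitneyu(
                xa, ya, use_continuity=True, alternative="two-sided",
                method="asymptotic",
            )
            p = float(min(res.pvalue, 1.0))
            used = "normal-approx-tie-corrected"

    med_x, q25_x, q75_x = summarize(xa)
    med_y, q25_y, q75_y = summarize(ya)
    return GroupComparison(
        variable=variable,
        label_x=labels[0],
        label_y=labels[1],
        n_x=n1,
        n_y=n2,
        median_x=med_x,
        q25_x=q25_x,
        q75_x=q75_x,
        median_y=med_y,
        q25_y=q25_y,
        q75_y=q75_y,
        u_statistic=u1,
        p_value=p,
        method=used,
        note=note,
    )


def _comparison_row(c: GroupComparison, **extra: object) -> dict:
    row = dict(extra)
    row.update(
        variable=c.variable,
        group_1=c.label_x,
        n_1=c.n_x,
        median_1=c.median_x,
        q25_1=c.q25_x,
        q75_1=c.q75_x,
        group_2=c.label_y,
        n_2=c.n_y,
        median_2=c.median_y,
        q25_2=c.q25_y,
        q75_2=c.q75_y,
        u_statistic=c.u_statistic,
        p_value=c.p_value,
        method=c.method,
    )
    return row


#: ResponseSummary attribute -> report variable name.
_TABLE2_VARIABLES = (
    ("cumulative_dose_mg", "cumulative_dose_mtx_mg"),
    ("improved_area", "improved_das28_area"),
    ("index_r", "index_r_per_mg"),
)


def build_table2(
    summaries: Iterable[ResponseSummary],
    labels: Mapping[str, str],
    method: str = "auto",
    exact_cap: int = 25,
    windows: Sequence[tuple[float, float]] = ((0.0, 3.0), (0.0, 6.0)),
) -> pd.DataFrame:
    """Good-vs-poor control comparisons of dose, improved area and index R.

    One row per (window, variable): 3 variables x 2 windows = 6 rows.
    ``labels`` maps patient id to ``"good"``/``"poor"``; every patient with
    a summary must carry a label and vice versa, else a join error lists
    the offending ids.
    """
    by_window: dict[tuple[float, float], list[ResponseSummary]] = {}
    for s in summaries:
        by_window.setdefault(tuple(s.window), []).append(s)
    rows = []
    for window in windows:
        window = (float(window[0]), float(window[1]))
        win_summaries = by_window.get(window, [])
        summary_ids = {s.patient_id for s in win_summaries}
        label_ids = set(labels)
        if summary_ids != label_ids:
            raise CohortJoinError(
                f"window {window}: summaries and labels disagree "
                f"(missing labels: {sorted(summary_ids - label_ids)}, "
                f"missing summaries: {sorted(label_ids - summary_ids)})"
            )
        good = [s for s in win_summaries if labels[s.patient_id] == "good"]
        poor = [s for s in win_summaries if labels[s.patient_id] == "poor"]
        for attr, name in _TABLE2_VARIABLES:
            c = mann_whitney(
                [getattr(s, attr) for s in good],
                [getattr(s, attr) for s in poor],
                method=method,
                exact_cap=exact_cap,
                variable=name,
                labels=("good", "poor"),
            )
            rows.append(
                _comparison_row(c, window=f"{window[0]:g}-{window[1]:g} months")
            )
    return pd.DataFrame(rows)


def build_table3(
    summaries: Iterable[ResponseSummary],
    genotype_groups: Mapping[str, Mapping[str, str]],
    method: str = "auto",
    exact_cap: int = 25,
    window: tuple[float, float] = (0.0, 6.0),
) -> pd.DataFrame:
    """Index R (0-6 months) compared across the five binary genotype groups.

    ``genotype_groups`` maps patient id -> {snp name -> group label} as
    produced by :func:`mtxresponse.classification.group_genotype`. A SNP
    with an empty group yields a row with ``p_value = NaN`` and a warning
    instead of crashing.
    """
    window = (float(window[0]), float(window[1]))
    r_by_id = {
        s.patient_id: s.index_r for s in summaries if tuple(s.window) == window
    }
    missing = [pid for pid in genotype_groups if pid not in r_by_id]
    if missing:
        raise CohortJoinError(
            f"no index R summary over window {window} for patients {sorted(missing)}"
        )
    rows = []
    for snp in SNP_ORDER:
        grouping = SNP_GROUPINGS[snp]
        ref = [
            r_by_id[pid]
            for pid, groups in genotype_groups.items()
            if groups.get(snp) == grouping.reference_group_label
        ]
        comp = [
            r_by_id[pid]
            for pid, groups in genotype_groups.items()
            if groups.get(snp) == grouping.comparison_group_label
        ]
        if not ref or not comp:
            warnings.warn(
                f"{snp}: a genotype group is empty "
                f"({grouping.reference_group_label}: {len(ref)}, "
                f"{grouping.comparison_group_label}: {len(comp)}); "
                "comparison skipped",
                stacklevel=2,
            )
            rows.append(
                dict(
                    snp=snp,
                    variable="index_r_per_mg",
                    group_1=grouping.reference_group_label,
                    n_1=len(ref),
                    median_1=np.nan,
                    q25_1=np.nan,
                    q75_1=np.nan,
                    group_2=grouping.comparison_group_label,
                    n_2=len(comp),
                    median_2=np.nan,
                    q25_2=np.nan,
                    q75_2=np.nan,
                    u_statistic=np.nan,
                    p_value=np.nan,
                    method="skipped-empty-group",
                )
            )
            continue
        c = mann_whitney(
            ref,
            comp,
            method=method,
            exact_cap=exact_cap,
            variable="index_r_per_mg",
            labels=(grouping.reference_group_label, grouping.comparison_group_label),
        )
        rows.append(_comparison_row(c, snp=snp))
    frame = pd.DataFrame(rows)
    return frame[
        ["snp"] + [c for c in frame.columns if c != "snp"]
    ]
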