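"""Mann-Whitney and summary-statistics tests, with a brute-force oracle.

The oracle enumerates every assignment of the pooled values to the two
group sizes and counts pairwise wins (half for ties) — a formulation
independent of the rank-sum / subset-DP route the implementation takes.
"""

import itertools
from math import comb

import numpy as np
import pytest

from mtxresponse import (
    ValidationError,
    build_table2,
    build_table3,
    mann_whitney,
    summarize,
)
from mtxresponse.scoring import ResponseSummary


def brute_force_p(x, y):
    """Exact two-sided p by enumeration and pairwise-win counting."""
    def u_stat(a, b):
        return sum(
            1.0 if ai > bj else 0.5 if ai == bj else 0.0
            for ai in a for bj in b
        )

    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    dev_obs = abs(u_stat(x, y) - mu)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n1 + n2) if i not in idx]
        if abs(u_stat(a, b) - mu) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_separated_triples_exact_p(self):
        # U = 0; the two fully separated assignments out of C(6,3) = 20
        c = mann_whitney([1, 2, 3], [4, 5, 6])
        assert c.u_statistic == 0.0
        assert c.p_value == pytest.approx(0.1)
        assert c.method == "exact-permutation"

    def test_identical_multisets_give_p_one(self):
        c = mann_whitney([1, 2, 3], [1, 2, 3])
        assert c.p_value == 1.0

    def test_all_values_identical_flagged(self):
        c = mann_whitney([5, 5], [5, 5, 5])
        assert c.p_value == 1.0
        assert "identical" in c.note

    def test_symmetry_and_u_complement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8)).round(1)
            y = rng.normal(size=rng.integers(2, 8)).round(1)
            cx = mann_whitney(x, y)
            cy = mann_whitney(y, x)
            assert cx.p_value == pytest.approx(cy.p_value, abs=1e-12)
            assert cx.u_statistic + cy.u_statistic == pytest.approx(
                len(x) * len(y)
            )

    def test_exact_equals_brute_force_enumeration(self):
        """Randomized battery, tie-free and heavily tied, n1+n2 <= 10."""
        rng = np.random.default_rng(123)
        for case in range(60):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 10 - n1 + 1) if n1 < 9 else 1)
            if case % 2:
                pool = rng.integers(0, 4, size=n1 + n2).astype(float)  # ties
            else:
                pool = rng.normal(size=n1 + n2)  # tie-free a.s.
            x, y = pool[:n1], pool[n1:]
            c = mann_whitney(x, y, method="exact")
            assert c.p_value == pytest.approx(brute_force_p(x, y), abs=1e-12)

    def test_exact_and_approx_agree_on_moderate_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(0.3, size=20)
            pe = mann_whitney(x, y, method="exact").p_value
            pa = mann_whitney(x, y, method="approx").p_value
            assert pe == pytest.approx(pa, abs=0.01)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(99)
        rates = []
        for shift in (0.0, 0.8, 1.6):
            rej = 0
            for _ in range(120):
                x = rng.normal(size=8)
                y = rng.normal(shift, size=8)
                if mann_whitney(x, y).p_value < 0.05:
                    rej += 1
            rates.append(rej / 120)
        assert rates[0] < rates[1] < rates[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])

    def test_auto_switches_to_approximation_above_cap(self):
        rng = np.random.default_rng(1)
        c = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert c.method == "normal-approx-tie-corrected"


class TestSummarize:
    def test_odd_length_median_is_middle(self):
        assert summarize([1, 2, 3, 4, 5])[0] == 3.0

    def test_index_r_scale_median(self):
        assert summarize([0.22, 0.25, 0.27])[0] == 0.25

    def test_quartiles_linear_interpolation_hand_check(self):
        # positions 1 + (n-1)q on {1,2,3,4}: q25 at 1.75, q75 at 3.25
        med, q25, q75 = summarize([1, 2, 3, 4])
        assert (med, q25, q75) == (2.5, 1.75, 3.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


def _summaries(values_by_window):
    out = []
    for window, values in values_by_window.items():
        for i, v in enumerate(values):
            out.append(
                ResponseSummary(
                    patient_id=f"P{i:02d}",
                    window=window,
                    cumulative_dose_mg=100.0 + v,
                    das28_auc=30.0 - v,
                    improved_area=v,
                    index_r=v / 100.0,
                )
            )
    return out


class TestReportBuilders:
    def test_table2_has_six_rows_three_variables_two_windows(self):
        values = list(range(10))
        summaries = _summaries({(0.0, 3.0): values, (0.0, 6.0): values})
        labels = {f"P{i:02d}": "good" if i < 4 else "poor" for i in range(10)}
        frame = build_table2(summaries, labels)
        assert len(frame) == 6
        assert set(frame["variable"]) == {
            "cumulative_dose_mtx_mg", "improved_das28_area", "index_r_per_mg",
        }

    def test_table2_identical_groups_give_p_one(self):
        values = [5.0] * 8
        summaries = _summaries({(0.0, 3.0): values, (0.0, 6.0): values})
        labels = {f"P{i:02d}": "good" if i < 4 else "poor" for i in range(8)}
        frame = build_table2(summaries, labels)
        assert (frame["p_value"] == 1.0).all()

    def test_table2_mismatched_ids_listed(self):
        summaries = _summaries({(0.0, 3.0): [1, 2, 3], (0.0, 6.0): [1, 2, 3]})
        labels = {"P00": "good", "P01": "poor"}  # P02 unlabelled
        with pytest.raises(Exception, match="P02"):
            build_table2(summaries, labels)

    def test_table3_five_rows_and_empty_group_skipped(self):
        summaries = _summaries({(0.0, 6.0): list(range(6))})
        groups = {}
        for i in range(6):
            groups[f"P{i:02d}"] = {
                "RFC1_80": "G/G" if i < 3 else "A allele",
                "FPGS_1994": "G allele" if i < 3 else "A/A",
                "GGH_401": "C/C" if i < 3 else "T allele",
                "MTHFR_1298": "A allele",  # comparison group empty
                "TYMS_UTR": "-6/-6" if i < 3 else "+6 allele",
            }
        with pytest.warns(UserWarning, match="MTHFR_1298"):
            frame = build_table3(summaries, groups)
        assert len(frame) == 5
        assert frame.loc[frame.snp == "MTHFR_1298", "method"].item() == "skipped-empty-group"
        assert frame["p_value"].notna().sum() == 4
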