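"""Fisher / Wilcoxon machinery and the full analysis report."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from isocooc import (
    fisher_iso_vs_noniso_context,
    iso_fraction_table,
    maf_comparisons,
    run_full_analysis,
    wilcoxon_rank_sum,
)
from isocooc.stats import ContextCountTable


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, N = a + b, a + b + c + d
    c1 = a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    denom = comb(N, c1)
    probs = {
        x: comb(r1, x) * comb(N - r1, c1 - x) / denom for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def rank_sum_oracle(x, y):
    """Two-sided rank-sum p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + j + 1) / 2  # mid-rank of the tied block
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    n1 = len(x)
    mean = sum(ranks) * n1 / len(pooled)
    obs = abs(sum(ranks[:n1]) - mean)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mean) >= obs - 1e-9:
            hits += 1
    return hits / total


def make_table(iso_iso, iso_non, non_iso, non_non, nonsyn=(0, 0)):
    rows = pd.DataFrame(
        {
            "context": ["ISO_CONTEXT", "NONISO_CONTEXT", "NONSYN_CONTEXT"],
            "iso": [iso_iso, non_iso, nonsyn[0]],
            "noniso": [iso_non, non_non, nonsyn[1]],
        }
    )
    rows["iso_pct"] = rows["iso"] / (rows["iso"] + rows["noniso"])
    return ContextCountTable(counts=rows.set_index("context"))


def classified_frame(rows):
    return pd.DataFrame(
        rows, columns=["mutation_type", "context_type", "maf", "in_cpg"]
    )


class TestIsoFractionTable:
    def test_counts_and_percentages(self):
        frame = classified_frame(
            [("ISOACCEPTING", "ISO_CONTEXT", 0.1, False)] * 10
            + [("NONISO_SYNONYMOUS", "ISO_CONTEXT", 0.1, False)] * 5
            + [("NONSYNONYMOUS", "ISO_CONTEXT", 0.1, False)] * 7
            + [("ISOACCEPTING", "NONISO_CONTEXT", 0.1, False)] * 7
        )
        table = iso_fraction_table(frame)
        assert table.counts.loc["ISO_CONTEXT", "iso"] == 10
        assert table.iso_pct("ISO_CONTEXT") == pytest.approx(10 / 15)
        assert table.iso_pct("NONISO_CONTEXT") == 1.0  # 7 iso, 0 noniso
        assert np.isnan(table.iso_pct("NONSYN_CONTEXT"))

    def test_no_context_rows_excluded(self):
        frame = classified_frame(
            [("ISOACCEPTING", "NO_CONTEXT", 0.1, False),
             ("ISOACCEPTING", "ISO_CONTEXT", 0.1, False)]
        )
        assert iso_fraction_table(frame).counts["iso"].sum() == 1


class TestFisher:
    def test_diagonal_table_worked_value(self):
        res = fisher_iso_vs_noniso_context(make_table(3, 0, 0, 3))
        assert res.p_value == pytest.approx(0.1)
        assert res.haldane_corrected

    def test_symmetric_table(self):
        res = fisher_iso_vs_noniso_context(make_table(5, 5, 5, 5))
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.haldane_corrected

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_iso_vs_noniso_context(make_table(0, 0, 5, 5))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 25, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = fisher_iso_vs_noniso_context(make_table(a, b, c, d))
            assert res.p_value == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-8
            ), (a, b, c, d)

    def test_worked_20_5_5_20(self):
        res = fisher_iso_vs_noniso_context(make_table(20, 5, 5, 20))
        assert res.p_value == pytest.approx(fisher_oracle(20, 5, 5, 20), rel=1e-9)


class TestWilcoxon:
    def test_extremal_small_groups(self):
        assert wilcoxon_rank_sum([0.1, 0.2], [0.3, 0.4]) == pytest.approx(1 / 3)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [0.1])

    @pytest.mark.parametrize(
        "n1,n2,tied", [(2, 2, False), (3, 4, False), (4, 4, True), (5, 5, True), (2, 8, False)]
    )
    def test_exact_p_matches_permutation_enumeration(self, n1, n2, tied):
        rng = np.random.default_rng(n1 * 10 + n2 + tied)
        for _ in range(5):
            pool = [0.1, 0.2, 0.3] if tied else None
            x = rng.choice(pool, n1) if tied else rng.random(n1)
            y = rng.choice(pool, n2) if tied else rng.random(n2)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                rank_sum_oracle(list(x), list(y))
            )

    def test_large_sample_branch_detects_clear_shift(self):
        rng = np.random.default_rng(0)
        x = rng.beta(3, 7, size=200)
        y = rng.beta(2, 8, size=200)
        assert wilcoxon_rank_sum(x, y) < 1e-4


class TestMafComparisons:
    def test_medians_and_anchored_tests(self):
        frame = classified_frame(
            [("ISOACCEPTING", "ISO_CONTEXT", m, False) for m in (0.1, 0.2, 0.4)]
            + [("ISOACCEPTING", "NONISO_CONTEXT", m, False) for m in (0.05, 0.1)]
            + [("ISOACCEPTING", "NONSYN_CONTEXT", m, False) for m in (0.1, 0.15)]
            + [("NONISO_SYNONYMOUS", "NONISO_CONTEXT", m, False) for m in (0.2, 0.3)]
            + [("NONISO_SYNONYMOUS", "ISO_CONTEXT", m, False) for m in (0.1, 0.2)]
            + [("NONISO_SYNONYMOUS", "NONSYN_CONTEXT", m, False) for m in (0.1, 0.2)]
            + [("NONSYNONYMOUS", "NONSYN_CONTEXT", 0.15, False)]
            + [("NONSENSE", "NONSYN_CONTEXT", 0.05, False)]
        )
        res = maf_comparisons(frame)
        assert res.medians_by_type["NONSENSE"] == pytest.approx(0.05)
        assert res.medians_by_type["NONSYNONYMOUS"] == pytest.approx(0.15)
        grp = res.medians_by_group
        iso_iso = grp[(grp.mutation_type == "ISOACCEPTING") & (grp.context == "ISO_CONTEXT")]
        assert iso_iso["median"].item() == pytest.approx(0.2)
        assert len(res.tests) == 4
        assert res.tests["p"].between(0, 1).all()

    def test_empty_group_reported_na_with_warning(self):
        frame = classified_frame(
            [("ISOACCEPTING", "ISO_CONTEXT", 0.1, False)]
        )
        res = maf_comparisons(frame)
        assert res.tests["p"].isna().all()
        assert res.warnings


class TestRunFullAnalysis:
    def test_cpg_exclusion_noop_on_cpg_free_data(self):
        frame = classified_frame(
            [("ISOACCEPTING", "ISO_CONTEXT", 0.1, False)] * 6
            + [("NONISO_SYNONYMOUS", "ISO_CONTEXT", 0.2, False)] * 3
            + [("ISOACCEPTING", "NONISO_CONTEXT", 0.15, False)] * 3
            + [("NONISO_SYNONYMOUS", "NONISO_CONTEXT", 0.25, False)] * 6
        )
        rep = run_full_analysis(frame, with_cpg_exclusion=True)
        pd.testing.assert_frame_equal(
            rep.arm("all")["context_table"].counts,
            rep.arm("non_cpg")["context_table"].counts,
        )
        assert rep.arm("all")["fisher"].p_value == rep.arm("non_cpg")["fisher"].p_value

    def test_cpg_arm_only_shrinks_counts(self):
        rows = (
            [("ISOACCEPTING", "ISO_CONTEXT", 0.1, True)] * 2
            + [("ISOACCEPTING", "ISO_CONTEXT", 0.1, False)] * 4
            + [("NONISO_SYNONYMOUS", "NONISO_CONTEXT", 0.2, False)] * 5
            + [("ISOACCEPTING", "NONISO_CONTEXT", 0.2, True)] * 2
            + [("NONISO_SYNONYMOUS", "ISO_CONTEXT", 0.1, False)] * 2
        )
        rep = run_full_analysis(classified_frame(rows), with_cpg_exclusion=True)
        full = rep.arm("all")["context_table"].counts
        non_cpg = rep.arm("non_cpg")["context_table"].counts
        assert (non_cpg[["iso", "noniso"]] <= full[["iso", "noniso"]]).all().all()
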