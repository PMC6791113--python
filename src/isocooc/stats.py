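"""Enrichment and MAF-spectrum statistics.

Two questions are asked of the classified mutations:

1. Is the fraction of isoaccepting mutations among synonymous mutations
   (iso%) higher in an isoaccepting context than in a nonisoaccepting
   context?  Tested with a two-sided Fisher's exact test on the 2x2
   table of (context: iso, noniso) x (mutation: iso, noniso).  The
   nonsynonymous-context column is reported descriptively only.

2. Do minor-allele-frequency spectra shift between contexts within a
   mutation class?  Tested with two-sided Wilcoxon rank-sum tests,
   exact (full permutation null over mid-ranks) for small groups,
   otherwise the normal approximation with tie and continuity
   corrections.

Raw p-values are reported; no multiple-testing correction (one test per
planned comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ContextType, MutationType

__all__ = [
    "ContextCountTable",
    "FisherResult",
    "iso_fraction_table",
    "fisher_iso_vs_noniso_context",
    "wilcoxon_rank_sum",
    "maf_comparisons",
    "run_full_analysis",
]

_MUTATION_CONTEXTS = [
    ContextType.ISO_CONTEXT.value,
    ContextType.NONISO_CONTEXT.value,
    ContextType.NONSYN_CONTEXT.value,
]
_SYNONYMOUS = [
    MutationType.ISOACCEPTING.value,
    MutationType.NONISO_SYNONYMOUS.value,
]


@dataclass
class ContextCountTable:
    """Counts of synonymous mutations by context, with iso% per context."""

    counts: pd.DataFrame  # index: context; columns: iso, noniso, iso_pct

    def iso_pct(self, context: str) -> float:
        return float(self.counts.loc[context, "iso_pct"])


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: List[List[int]]
    haldane_corrected: bool = False


def iso_fraction_table(classified: pd.DataFrame) -> ContextCountTable:
    """Tabulate iso vs noniso synonymous mutations per context.

    Sites with NO_CONTEXT or EXCLUDED_POLYMORPHIC_CONTEXT are left out.
    A context with no synonymous mutations reports iso_pct = NaN.
    """
    syn = classified[classified["mutation_type"].isin(_SYNONYMOUS)]
    rows = []
    for ctx in _MUTATION_CONTEXTS:
        sub = syn[syn["context_type"] == ctx]
        n_iso = int((sub["mutation_type"] == MutationType.ISOACCEPTING.value).sum())
        n_noniso = len(sub) - n_iso
        denom = n_iso + n_noniso
        rows.append(
            {
                "context": ctx,
                "iso": n_iso,
                "noniso": n_noniso,
                "iso_pct": n_iso / denom if denom else float("nan"),
            }
        )
    return ContextCountTable(counts=pd.DataFrame(rows).set_index("context"))


def fisher_iso_vs_noniso_context(table: ContextCountTable) -> FisherResult:
    """Two-sided Fisher's exact test: iso vs noniso context.

    The 2x2 table is [[iso-ctx iso, iso-ctx noniso],
    [noniso-ctx iso, noniso-ctx noniso]].  The sample odds ratio gets a
    0.5 Haldane correction only when a cell is zero (flagged).  A zero
    margin makes the test undefined and raises.
    """
    a = int(table.counts.loc[ContextType.ISO_CONTEXT.value, "iso"])
    b = int(table.counts.loc[ContextType.ISO_CONTEXT.value, "noniso"])
    c = int(table.counts.loc[ContextType.NONISO_CONTEXT.value, "iso"])
    d = int(table.counts.loc[ContextType.NONISO_CONTEXT.value, "noniso"])
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("Fisher test undefined: a table margin is zero")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return FisherResult(
        odds_ratio=float(odds),
        p_value=float(p),
        table=[[a, b], [c, d]],
        haldane_corrected=haldane,
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments.

    Mid-ranks handle ties; p is the fraction of the C(n1+n2, n1)
    equally likely assignments whose rank-sum deviates from its null
    mean by at least as much as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n = len(x), len(pooled)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / n
    d_obs = abs(obs - mean) - 1e-9
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= d_obs:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation null when both groups have n <= 8 or the pooled
    sample has at most 10 observations (ties handled with mid-ranks);
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if (len(x) <= 8 and len(y) <= 8) or len(x) + len(y) <= 10:
        return _exact_rank_sum_p(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


@dataclass
class MafComparisons:
    medians_by_type: Dict[str, float]
    medians_by_group: pd.DataFrame  # (mutation_type, context) -> median, n
    tests: pd.DataFrame  # mutation_type, context_a, context_b, n_a, n_b, p
    warnings: List[str] = field(default_factory=list)


def maf_comparisons(classified: pd.DataFrame) -> MafComparisons:
    """MAF medians by type/group and anchored rank-sum comparisons.

    Medians by type pool isoaccepting + nonisoaccepting as synonymous.
    Comparisons anchor each synonymous class to its "own" context:
    isoaccepting-mutation MAF in the iso context against every other
    context, and nonisoaccepting-mutation MAF in the noniso context
    against every other context.
    """
    warns: List[str] = []

    def med(frame: pd.DataFrame) -> float:
        return float(frame["maf"].median()) if len(frame) else float("nan")

    syn = classified[classified["mutation_type"].isin(_SYNONYMOUS)]
    medians_by_type = {
        "SYNONYMOUS": med(syn),
        "NONSYNONYMOUS": med(
            classified[classified["mutation_type"] == MutationType.NONSYNONYMOUS.value]
        ),
        "NONSENSE": med(
            classified[classified["mutation_type"] == MutationType.NONSENSE.value]
        ),
    }

    groups = []
    for mt in _SYNONYMOUS:
        for ctx in _MUTATION_CONTEXTS:
            sub = classified[
                (classified["mutation_type"] == mt)
                & (classified["context_type"] == ctx)
            ]
            groups.append(
                {"mutation_type": mt, "context": ctx, "n": len(sub), "median": med(sub)}
            )
    medians_by_group = pd.DataFrame(groups)

    anchors = [
        (MutationType.ISOACCEPTING.value, ContextType.ISO_CONTEXT.value),
        (MutationType.NONISO_SYNONYMOUS.value, ContextType.NONISO_CONTEXT.value),
    ]
    tests = []
    for mt, anchor in anchors:
        base = classified[
            (classified["mutation_type"] == mt)
            & (classified["context_type"] == anchor)
        ]["maf"].to_numpy()
        for ctx in _MUTATION_CONTEXTS:
            if ctx == anchor:
                continue
            other = classified[
                (classified["mutation_type"] == mt)
                & (classified["context_type"] == ctx)
            ]["maf"].to_numpy()
            if len(base) == 0 or len(other) == 0:
                warns.append(
                    f"empty group for {mt} in {anchor if len(base)==0 else ctx}; "
                    "comparison reported as NA"
                )
                p = float("nan")
            else:
                p = wilcoxon_rank_sum(base, other)
            tests.append(
                {
                    "mutation_type": mt,
                    "context_a": anchor,
                    "context_b": ctx,
                    "n_a": len(base),
                    "n_b": len(other),
                    "p": p,
                }
            )
    return MafComparisons(
        medians_by_type=medians_by_type,
        medians_by_group=medians_by_group,
        tests=pd.DataFrame(tests),
        warnings=warns,
    )


@dataclass
class AnalysisReport:
    """Complete result bundle, optionally with a CpG-excluded arm."""

    arms: Dict[str, dict]

    def arm(self, name: str = "all") -> dict:
        return self.arms[name]


def _analyse_arm(classified: pd.DataFrame) -> dict:
    table = iso_fraction_table(classified)
    try:
        fisher: Optional[FisherResult] = fisher_iso_vs_noniso_context(table)
    except ValueError:
        fisher = None
    return {
        "context_table": table,
        "fisher": fisher,
        "maf": maf_comparisons(classified),
        "n_sites": len(classified),
    }


def run_full_analysis(
    classified: pd.DataFrame, with_cpg_exclusion: bool = False
) -> AnalysisReport:
    """Run the iso% and MAF analyses, optionally repeated on non-CpG sites.

    ``classified`` is the frame from
    :func:`isocooc.classify.classified_to_frame`.  The CpG arm keeps only
    sites whose reference base is outside any CG dinucleotide.
    """
    arms = {"all": _analyse_arm(classified)}
    if with_cpg_exclusion:
        if classified["in_cpg"].isna().any():
            raise ValueError("CpG arm requested but in_cpg is not annotated")
        arms["non_cpg"] = _analyse_arm(classified[~classified["in_cpg"].astype(bool)])
    return AnalysisReport(arms=arms)
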