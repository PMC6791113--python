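"""Read-backed pairwise linkage disequilibrium.

For two biallelic sites covered by the same reads, the reads covering
BOTH sites are tallied by allele combination (R = reference, M = mutant)
into RR, RM, MR, MM with N = RR + RM + MR + MM.  Marginals are
P1 = (RR+RM)/N, Q1 = (MR+MM)/N, P2 = (RR+MR)/N, Q2 = (RM+MM)/N, the
disequilibrium is D = (RR*MM - RM*MR)/N^2 and the squared correlation is
r^2 = D^2 / (P1*Q1*P2*Q2), which lies in [0, 1].  A high r^2 between
sites seen on the same RNA-seq fragments indicates genuine co-inherited
DNA variants rather than independent sequencing or RNA-level errors.

Reads covering only one of the two sites, or showing a third allele at
either site, are excluded from N (tallied separately).  Paired-end mates
sharing a read id are treated as one fragment by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .io_ingest import VariantSite

__all__ = [
    "LdPairCounts",
    "LdResult",
    "haplotype_counts",
    "compute_ld",
    "pairwise_ld",
    "read_alleles_tsv",
]


@dataclass(frozen=True)
class LdPairCounts:
    """Co-covering read counts for one site pair."""

    site1: str
    site2: str
    rr: int
    rm: int
    mr: int
    mm: int
    n_one_site: int = 0     # reads covering exactly one of the sites
    n_other_allele: int = 0  # reads with a third allele at either site

    @property
    def n(self) -> int:
        return self.rr + self.rm + self.mr + self.mm

    @property
    def computable(self) -> bool:
        return self.n > 0


@dataclass(frozen=True)
class LdResult:
    p1: float
    q1: float
    p2: float
    q2: float
    d: float
    r2: Optional[float]  # None when a site is monomorphic among the reads


def site_id(site: VariantSite) -> str:
    return f"{site.gene_id}:{site.pos}"


def read_alleles_tsv(path) -> pd.DataFrame:
    """Read a per-read allele table (read_id, site_id, base)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"read_id", "site_id", "base"}
    if not expected.issubset(df.columns):
        raise ValueError(f"read-allele table must have columns {sorted(expected)}")
    return df


def haplotype_counts(
    read_alleles: pd.DataFrame,
    site1: VariantSite,
    site2: VariantSite,
    mate_mode: str = "fragment",
) -> LdPairCounts:
    """Tally RR/RM/MR/MM over reads observing both sites.

    ``read_alleles`` has columns read_id, site_id, base; site ids are
    ``gene:pos``.  With ``mate_mode="fragment"`` (default) paired-end
    mates sharing a read id count as one covering unit; with ``"read"``
    a trailing ``/1`` or ``/2`` mate suffix keeps mates separate.
    """
    if mate_mode not in ("fragment", "read"):
        raise ValueError("mate_mode must be 'fragment' or 'read'")
    id1, id2 = site_id(site1), site_id(site2)
    sub = read_alleles[read_alleles["site_id"].isin([id1, id2])].copy()
    if mate_mode == "fragment":
        sub["read_id"] = sub["read_id"].str.replace(r"/[12]$", "", regex=True)
    tallies = {"RR": 0, "RM": 0, "MR": 0, "MM": 0}
    n_one = n_other = 0
    for _, grp in sub.groupby("read_id"):
        obs: Dict[str, str] = {}
        for _, row in grp.iterrows():
            obs[row["site_id"]] = row["base"].upper()
        if id1 not in obs or id2 not in obs:
            n_one += 1
            continue
        code = ""
        for sid, site in ((id1, site1), (id2, site2)):
            if obs[sid] == site.ref_base:
                code += "R"
            elif obs[sid] == site.alt_base:
                code += "M"
        if len(code) == 2:
            tallies[code] += 1
        else:
            n_other += 1
    return LdPairCounts(
        site1=id1,
        site2=id2,
        rr=tallies["RR"],
        rm=tallies["RM"],
        mr=tallies["MR"],
        mm=tallies["MM"],
        n_one_site=n_one,
        n_other_allele=n_other,
    )


def compute_ld(counts: LdPairCounts) -> LdResult:
    """D and r^2 from co-covering read counts (requires N > 0)."""
    n = counts.n
    if n == 0:
        raise ValueError("LD undefined: no reads cover both sites")
    p1 = (counts.rr + counts.rm) / n
    q1 = (counts.mr + counts.mm) / n
    p2 = (counts.rr + counts.mr) / n
    q2 = (counts.rm + counts.mm) / n
    d = (counts.rr * counts.mm - counts.rm * counts.mr) / n**2
    denom = p1 * q1 * p2 * q2
    r2 = (d * d) / denom if denom > 0 else None
    return LdResult(p1=p1, q1=q1, p2=p2, q2=q2, d=d, r2=r2)


def pairwise_ld(
    read_alleles: pd.DataFrame,
    sites: Sequence[VariantSite],
    mate_mode: str = "fragment",
) -> Tuple[pd.DataFrame, dict]:
    """r^2 for every computable within-gene site pair, plus a summary.

    Sites on different genes are never paired.  The summary reports the
    median r^2 over computable pairs and the number of pairs that were
    non-computable (no co-covering reads or monomorphic among them).
    """
    by_gene: Dict[str, List[VariantSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    rows = []
    n_noncomputable = 0
    for gene, group in by_gene.items():
        for s1, s2 in combinations(group, 2):
            counts = haplotype_counts(read_alleles, s1, s2, mate_mode=mate_mode)
            if not counts.computable:
                n_noncomputable += 1
                continue
            res = compute_ld(counts)
            if res.r2 is None:
                n_noncomputable += 1
                continue
            rows.append(
                {
                    "gene": gene,
                    "site1": counts.site1,
                    "site2": counts.site2,
                    "n": counts.n,
                    "d": res.d,
                    "r2": res.r2,
                }
            )
    matrix = pd.DataFrame(rows, columns=["gene", "site1", "site2", "n", "d", "r2"])
    summary = {
        "n_pairs": len(matrix),
        "n_noncomputable": n_noncomputable,
        "median_r2": float(matrix["r2"].median()) if len(matrix) else float("nan"),
    }
    if not len(matrix):
        import warnings

        warnings.warn("no computable site pair", stacklevel=2)
    return matrix, summary
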