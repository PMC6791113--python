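"""Mutation-type and codon-context classification, plus the genome census.

Every filtered mutation gets a *functional type* — the relation of the
mutated codon to the reference codon (isoaccepting / nonisoaccepting
synonymous / nonsynonymous / nonsense) — and a *context type* — the
relation of the focal codon to the codon immediately upstream of it.
A genome-wide census classifies every codon (except the first of each
CDS) against its predecessor, which yields the exact identity

    n_iso + n_noniso + n_nonsyn + n_ambiguous + n_genes = n_codons

because each gene contributes exactly one unclassified first codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .codon_model import (
    STANDARD_CODE,
    STOP,
    GeneticCode,
    IsoacceptorMap,
    Relation,
    codon_relationship,
)
from .io_ingest import CdsRecord, CdsSet, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "MutationType",
    "ContextType",
    "ClassifiedMutation",
    "ContextCensus",
    "classify_mutation",
    "classify_context",
    "classify_mutations",
    "genome_context_census",
    "cpg_annotate",
    "cpg_content",
    "classified_to_frame",
]


class MutationType(str, Enum):
    ISOACCEPTING = "ISOACCEPTING"
    NONISO_SYNONYMOUS = "NONISO_SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    NONSENSE = "NONSENSE"
    STOP_LOSS = "STOP_LOSS"  # inside the terminal stop; outside the tally


class ContextType(str, Enum):
    ISO_CONTEXT = "ISO_CONTEXT"
    NONISO_CONTEXT = "NONISO_CONTEXT"
    NONSYN_CONTEXT = "NONSYN_CONTEXT"
    NO_CONTEXT = "NO_CONTEXT"
    EXCLUDED_POLYMORPHIC_CONTEXT = "EXCLUDED_POLYMORPHIC_CONTEXT"


_REL_TO_CONTEXT = {
    Relation.ISOACCEPTING: ContextType.ISO_CONTEXT,
    Relation.NONISO_SYNONYMOUS: ContextType.NONISO_CONTEXT,
    Relation.NONSYNONYMOUS: ContextType.NONSYN_CONTEXT,
}


@dataclass(frozen=True)
class ClassifiedMutation:
    site: VariantSite
    ref_codon: str
    alt_codon: str
    mutation_type: MutationType
    context_type: ContextType
    in_cpg: Optional[bool] = None


def _codons_of(site: VariantSite, cds: CdsRecord) -> Tuple[str, str]:
    ref_codon = cds.codon(site.codon_index)
    off = site.offset_in_codon
    if ref_codon[off] != site.ref_base:
        raise ValueError(
            f"{site.gene_id}:{site.pos}: ref base {site.ref_base} does not "
            f"match CDS codon {ref_codon}"
        )
    alt_codon = ref_codon[:off] + site.alt_base + ref_codon[off + 1 :]
    return ref_codon, alt_codon


def classify_mutation(
    site: VariantSite,
    cds: CdsRecord,
    iso_map: IsoacceptorMap,
    code: GeneticCode = STANDARD_CODE,
) -> MutationType:
    """Functional type of a single-base mutation.

    A mutation inside the terminal stop codon is STOP_LOSS and is kept
    out of the four-way tally downstream.
    """
    ref_codon, alt_codon = _codons_of(site, cds)
    aa_ref = code.codon_to_amino_acid[ref_codon]
    if aa_ref == STOP:
        return MutationType.STOP_LOSS
    aa_alt = code.codon_to_amino_acid[alt_codon]
    if aa_alt == STOP:
        return MutationType.NONSENSE
    if aa_alt != aa_ref:
        return MutationType.NONSYNONYMOUS
    if alt_codon in iso_map.isoacceptors[ref_codon]:
        return MutationType.ISOACCEPTING
    return MutationType.NONISO_SYNONYMOUS


def classify_context(
    site: VariantSite,
    cds: CdsRecord,
    iso_map: IsoacceptorMap,
    polymorphic_codons: Optional[Set[Tuple[str, int]]] = None,
    code: GeneticCode = STANDARD_CODE,
    use_alt_focal: bool = False,
) -> ContextType:
    """Context type: relation of the focal codon to its upstream codon.

    The focal codon is the REFERENCE codon containing the site (set
    ``use_alt_focal=True`` to use the mutated codon instead).  A site in
    the first codon has NO_CONTEXT; a previous codon that itself carries
    a polymorphic site (``polymorphic_codons`` is a set of 1-based
    (gene, codon_index) pairs) gives EXCLUDED_POLYMORPHIC_CONTEXT.
    """
    ci = site.codon_index
    if ci == 1:
        return ContextType.NO_CONTEXT
    if polymorphic_codons and (site.gene_id, ci - 1) in polymorphic_codons:
        return ContextType.EXCLUDED_POLYMORPHIC_CONTEXT
    prev = cds.codon(ci - 1)
    ref_codon, alt_codon = _codons_of(site, cds)
    focal = alt_codon if use_alt_focal else ref_codon
    if "N" in prev or "N" in focal:
        return ContextType.NO_CONTEXT
    return _REL_TO_CONTEXT[codon_relationship(prev, focal, iso_map, code)]


def classify_mutations(
    sites: Sequence[VariantSite],
    cds_set: CdsSet,
    iso_map: IsoacceptorMap,
    code: GeneticCode = STANDARD_CODE,
    use_alt_focal: bool = False,
    annotate_cpg: bool = True,
) -> List[ClassifiedMutation]:
    """Classify a set of filtered sites end to end.

    ``polymorphic_codons`` for the context exclusion is derived from the
    input sites themselves.  STOP_LOSS sites are logged and excluded.
    """
    poly = {(s.gene_id, s.codon_index) for s in sites}
    out: List[ClassifiedMutation] = []
    n_stop_loss = 0
    for s in sites:
        cds = cds_set[s.gene_id]
        mtype = classify_mutation(s, cds, iso_map, code)
        if mtype is MutationType.STOP_LOSS:
            n_stop_loss += 1
            continue
        ctx = classify_context(
            s, cds, iso_map, polymorphic_codons=poly, code=code,
            use_alt_focal=use_alt_focal,
        )
        ref_codon, alt_codon = _codons_of(s, cds)
        out.append(
            ClassifiedMutation(
                site=s,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                mutation_type=mtype,
                context_type=ctx,
                in_cpg=_in_cpg(cds.sequence, s.pos) if annotate_cpg else None,
            )
        )
    if n_stop_loss:
        logger.info("%d stop-loss site(s) excluded from the tally", n_stop_loss)
    return out


@dataclass
class ContextCensus:
    """Genome-wide counts of codon-pair relations.

    Every codon except the first of each CDS is classified against its
    immediate predecessor; terminal stop codons participate (any pair
    involving a stop is nonsynonymous); pairs touching an N-containing
    codon go to ``n_ambiguous``.
    """

    n_genes: int
    n_codons: int
    n_iso: int
    n_noniso: int
    n_nonsyn: int
    n_ambiguous: int = 0
    per_gene: Dict[str, Tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def identity_holds(self) -> bool:
        return (
            self.n_iso
            + self.n_noniso
            + self.n_nonsyn
            + self.n_ambiguous
            + self.n_genes
            == self.n_codons
        )


def _relation_lookup(iso_map: IsoacceptorMap, code: GeneticCode):
    """Precompute relation for all 64x64 codon pairs (census fast path)."""
    codons = sorted(code.codon_to_amino_acid)
    table = {}
    for c1 in codons:
        for c2 in codons:
            table[(c1, c2)] = codon_relationship(c1, c2, iso_map, code)
    return table


def genome_context_census(
    cds_set: CdsSet,
    iso_map: IsoacceptorMap,
    code: GeneticCode = STANDARD_CODE,
) -> ContextCensus:
    """Classify every codon of every CDS against its predecessor."""
    rel = _relation_lookup(iso_map, code)
    n_codons = n_iso = n_noniso = n_nonsyn = n_amb = 0
    per_gene = {}
    for cds in cds_set:
        seq = cds.sequence
        nc = len(seq) // 3
        n_codons += nc
        g_iso = g_noniso = g_nonsyn = g_amb = 0
        prev = seq[0:3]
        for i in range(1, nc):
            cur = seq[3 * i : 3 * i + 3]
            if "N" in prev or "N" in cur:
                g_amb += 1
            else:
                r = rel[(prev, cur)]
                if r is Relation.ISOACCEPTING:
                    g_iso += 1
                elif r is Relation.NONISO_SYNONYMOUS:
                    g_noniso += 1
                else:
                    g_nonsyn += 1
            prev = cur
        n_iso += g_iso
        n_noniso += g_noniso
        n_nonsyn += g_nonsyn
        n_amb += g_amb
        per_gene[cds.gene_id] = (g_iso, g_noniso, g_nonsyn, g_amb)
    return ContextCensus(
        n_genes=len(cds_set),
        n_codons=n_codons,
        n_iso=n_iso,
        n_noniso=n_noniso,
        n_nonsyn=n_nonsyn,
        n_ambiguous=n_amb,
        per_gene=per_gene,
    )


def _in_cpg(seq: str, pos: int) -> bool:
    """True iff the 1-based position sits in a CG dinucleotide."""
    base = seq[pos - 1]
    if base == "C" and pos < len(seq) and seq[pos] == "G":
        return True
    if base == "G" and pos >= 2 and seq[pos - 2] == "C":
        return True
    return False


def cpg_annotate(
    sites: Iterable[VariantSite], cds_set: CdsSet
) -> List[bool]:
    """Per-site flags: reference base participates in a CG dinucleotide."""
    return [_in_cpg(cds_set[s.gene_id].sequence, s.pos) for s in sites]


def cpg_content(cds_set: CdsSet) -> Tuple[float, float]:
    """Observed vs expected CpG frequency over a CDS set.

    Observed: CG dinucleotides over all within-CDS adjacent base pairs.
    Expected: f(C) * f(G) from the pooled mononucleotide frequencies.
    """
    n_pairs = n_cg = n_bases = n_c = n_g = 0
    for cds in cds_set:
        seq = cds.sequence
        if not seq:
            raise ValueError(f"empty sequence for gene {cds.gene_id}")
        n_bases += len(seq)
        n_c += seq.count("C")
        n_g += seq.count("G")
        n_pairs += len(seq) - 1
        n_cg += seq.count("CG")
    if n_pairs == 0 or n_bases == 0:
        raise ValueError("CDS set has no adjacent base pairs")
    observed = n_cg / n_pairs
    expected = (n_c / n_bases) * (n_g / n_bases)
    return observed, expected


def classified_to_frame(classified: Sequence[ClassifiedMutation]) -> pd.DataFrame:
    """Tabulate classified mutations (one row per site)."""
    return pd.DataFrame(
        {
            "gene": [c.site.gene_id for c in classified],
            "pos": [c.site.pos for c in classified],
            "ref": [c.site.ref_base for c in classified],
            "alt": [c.site.alt_base for c in classified],
            "level": [c.site.level for c in classified],
            "maf": [c.site.maf for c in classified],
            "ref_codon": [c.ref_codon for c in classified],
            "alt_codon": [c.alt_codon for c in classified],
            "mutation_type": [c.mutation_type.value for c in classified],
            "context_type": [c.context_type.value for c in classified],
            "in_cpg": [c.in_cpg for c in classified],
        }
    )
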