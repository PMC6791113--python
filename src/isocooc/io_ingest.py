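"""CDS FASTA / variant-table ingestion, site filters, and MAF.

Coordinates are 1-based positions on the CDS (VCF convention); codon
indices are 1-based; the CDS is always the coding strand.

The variant filters mirror an RNA-seq polymorphism-calling workflow on
CDS references: only bi-allelic SNVs, alternative-allele level within
[0.02, 0.98], and no two mutations in the same or adjacent codons of one
gene (such clusters make the codon-context assignment ambiguous, so every
member of a cluster is removed).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CdsRecord",
    "CdsSet",
    "VariantSite",
    "read_cds_fasta",
    "load_variants",
    "filter_variants",
    "compute_maf",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CDS_ALPHABET = set("ACGTN")

# CDS record flags
NOT_TRIPLET = "NOT_TRIPLET"
INTERNAL_STOP = "INTERNAL_STOP"
INVALID_ALPHABET = "INVALID_ALPHABET"

# variant flags / drop reasons
REF_MISMATCH = "REF_MISMATCH"
NOT_BIALLELIC = "NOT_BIALLELIC"
NOT_SNV = "NOT_SNV"
LEVEL_OUT_OF_RANGE = "LEVEL_OUT_OF_RANGE"
CLUSTERED = "CLUSTERED"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence (the longest transcript of its gene)."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codon(self, codon_index: int) -> str:
        """The 1-based ``codon_index``-th codon."""
        i = (codon_index - 1) * 3
        return self.sequence[i : i + 3]


@dataclass
class CdsSet:
    """Longest-CDS-per-gene records plus flagged/excluded ones."""

    records: Dict[str, CdsRecord]
    flagged: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> CdsRecord:
        return self.records[gene_id]


@dataclass(frozen=True)
class VariantSite:
    """One candidate mutation in CDS coordinates.

    ``level`` is the alternative-allele fraction x; the minor allele
    frequency is ``min(x, 1-x)``.
    """

    gene_id: str
    pos: int  # 1-based on the CDS
    ref_base: str
    alt_base: str
    level: float
    flags: frozenset = frozenset()

    @property
    def maf(self) -> float:
        return compute_maf(self.level)

    @property
    def codon_index(self) -> int:
        """1-based index of the codon containing this site."""
        return (self.pos + 2) // 3

    @property
    def offset_in_codon(self) -> int:
        """0-based position of the site within its codon."""
        return (self.pos - 1) % 3


def compute_maf(level: float) -> float:
    """Minor allele frequency from an alternative-allele level x.

    MAF = x for x <= 0.5 and 1 - x otherwise; defined on 0 < x < 1.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"allele level must lie in (0, 1): {level}")
    return min(level, 1.0 - level)


_GENE_TAG_RE = re.compile(r"gene:(\S+)")
_TRANSCRIPT_SUFFIX_RE = re.compile(r"_T\d+$|\.\d+$")


def _default_gene_id(record_id: str, description: str) -> str:
    m = _GENE_TAG_RE.search(description)
    if m:
        return m.group(1)
    return _TRANSCRIPT_SUFFIX_RE.sub("", record_id)


def _cds_flag(seq: str) -> Optional[str]:
    if set(seq) - _CDS_ALPHABET:
        return INVALID_ALPHABET
    if len(seq) % 3 != 0:
        return NOT_TRIPLET
    for i in range(0, len(seq) - 3, 3):  # internal codons only
        if seq[i : i + 3] in _STOPS:
            return INTERNAL_STOP
    return None


def read_cds_fasta(path, gene_regex: Optional[str] = None) -> CdsSet:
    """Read a CDS FASTA keeping one record per gene (the longest CDS).

    Gene identifiers come from an Ensembl-plants style ``gene:`` tag in
    the header, falling back to the record id with a trailing ``_T\\d+``
    or ``.\\d+`` transcript suffix stripped; ``gene_regex`` (one capture
    group, matched against the full header) overrides both.  Length ties
    break lexicographically by transcript id.  Records that are not a
    multiple of 3, contain a non-ACGTN character, or carry an internal
    stop codon are flagged and excluded, with a logged count.
    """
    pattern = re.compile(gene_regex) if gene_regex else None
    best: Dict[str, CdsRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if pattern is not None:
            m = pattern.search(header)
            if not m:
                raise ValueError(
                    f"header does not match gene regex: {header!r}"
                )
            gene = m.group(1)
        else:
            gene = _default_gene_id(rec.id, header)
        cand = CdsRecord(
            gene_id=gene, transcript_id=rec.id, sequence=str(rec.seq).upper()
        )
        cur = best.get(gene)
        if (
            cur is None
            or len(cand) > len(cur)
            or (len(cand) == len(cur) and cand.transcript_id < cur.transcript_id)
        ):
            best[gene] = cand
    kept: Dict[str, CdsRecord] = {}
    flagged: Dict[str, str] = {}
    for gene, rec in best.items():
        flag = _cds_flag(rec.sequence)
        if flag is None:
            kept[gene] = rec
        else:
            flagged[gene] = flag
    if not kept and not flagged:
        logger.warning("no records parsed from %s", path)
    if flagged:
        logger.info(
            "%d CDS record(s) flagged and excluded: %s",
            len(flagged),
            sorted(set(flagged.values())),
        )
    return CdsSet(records=kept, flagged=flagged)


def _site_flags(
    gene: str, pos: int, ref: str, alt: str, cds_set: CdsSet
) -> frozenset:
    flags = set()
    alt_alleles = alt.split(",")
    if len(alt_alleles) > 1:
        flags.add(NOT_BIALLELIC)
    if len(ref) != 1 or any(len(a) != 1 for a in alt_alleles):
        flags.add(NOT_SNV)
    if gene not in cds_set:
        flags.add(REF_MISMATCH)
    elif len(ref) == 1 and (
        pos < 1
        or pos > len(cds_set[gene].sequence)
        or cds_set[gene].sequence[pos - 1] != ref
    ):
        flags.add(REF_MISMATCH)
    return frozenset(flags)


def _parse_tsv(path) -> List[Tuple[str, int, str, str, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns "
                    "(gene, pos, ref, alt, level)"
                )
            if lineno == 1 and not parts[1].isdigit():
                continue  # header
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        parts[2].upper(),
                        parts[3].upper(),
                        float(parts[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    return rows


def _parse_vcf(path) -> List[Tuple[str, int, str, str, float]]:
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        level = v.INFO.get("AF")
        if level is None:
            raise ValueError(
                f"VCF record {v.CHROM}:{v.POS} lacks an INFO/AF allele level"
            )
        if isinstance(level, tuple):
            level = level[0]
        alt = ",".join(v.ALT)
        rows.append((v.CHROM, v.POS, v.REF.upper(), alt.upper(), float(level)))
    return rows


def load_variants(path, cds_set: CdsSet) -> List[VariantSite]:
    """Load a variant table (TSV or VCF) against a CDS set.

    TSV columns: gene, pos (1-based CDS), ref, alt, level.  VCF: CHROM is
    the transcript or gene id, POS is on the CDS, the allele level is
    INFO/AF.  Every parseable row becomes a :class:`VariantSite`; rows
    whose gene is unknown or whose ref base disagrees with the CDS are
    flagged ``REF_MISMATCH``, multi-allelic records (VCF multi-ALT, or
    several TSV rows sharing gene+pos) are flagged ``NOT_BIALLELIC``.
    Flags turn into drop reasons in :func:`filter_variants`.
    """
    text = str(path)
    rows = _parse_vcf(path) if text.endswith((".vcf", ".vcf.gz")) else _parse_tsv(path)

    # map transcript-style CHROMs back to gene ids
    def resolve(gene: str) -> str:
        if gene in cds_set:
            return gene
        stripped = _TRANSCRIPT_SUFFIX_RE.sub("", gene)
        return stripped if stripped in cds_set else gene

    counts: Dict[Tuple[str, int], int] = {}
    resolved = []
    for gene, pos, ref, alt, level in rows:
        gene = resolve(gene)
        resolved.append((gene, pos, ref, alt, level))
        counts[(gene, pos)] = counts.get((gene, pos), 0) + 1

    sites = []
    n_mismatch = 0
    for gene, pos, ref, alt, level in resolved:
        flags = set(_site_flags(gene, pos, ref, alt, cds_set))
        if counts[(gene, pos)] > 1:
            flags.add(NOT_BIALLELIC)
        if REF_MISMATCH in flags:
            n_mismatch += 1
        sites.append(
            VariantSite(
                gene_id=gene,
                pos=pos,
                ref_base=ref,
                alt_base=alt,
                level=level,
                flags=frozenset(flags),
            )
        )
    if n_mismatch:
        logger.info("%d site(s) flagged REF_MISMATCH", n_mismatch)
    return sites


def filter_variants(
    sites: Sequence[VariantSite],
    min_level: float = 0.02,
    max_level: float = 0.98,
) -> Tuple[List[VariantSite], List[Tuple[VariantSite, str]]]:
    """Apply the polymorphic-site filters.

    Drops, in priority order with one primary reason per site:

    1. ``REF_MISMATCH`` — unknown gene or ref base disagreeing with the CDS;
    2. ``NOT_BIALLELIC`` / ``NOT_SNV`` — multi-allelic or non-SNV records;
    3. ``LEVEL_OUT_OF_RANGE`` — level outside [min_level, max_level];
    4. ``CLUSTERED`` — every member of any pair of surviving sites lying
       in the same or adjacent codons of one gene.

    Returns ``(kept, dropped)``; the two lists partition the input.
    Filtering is idempotent.
    """
    kept: List[VariantSite] = []
    dropped: List[Tuple[VariantSite, str]] = []
    survivors: List[VariantSite] = []
    for s in sites:
        if REF_MISMATCH in s.flags:
            dropped.append((s, REF_MISMATCH))
        elif NOT_BIALLELIC in s.flags:
            dropped.append((s, NOT_BIALLELIC))
        elif NOT_SNV in s.flags:
            dropped.append((s, NOT_SNV))
        elif not (min_level <= s.level <= max_level):
            dropped.append((s, LEVEL_OUT_OF_RANGE))
        else:
            survivors.append(s)

    by_gene: Dict[str, List[VariantSite]] = {}
    for s in survivors:
        by_gene.setdefault(s.gene_id, []).append(s)
    clustered = set()
    for gene, group in by_gene.items():
        idx = sorted((s.codon_index, i) for i, s in enumerate(group))
        for (c1, i1), (c2, i2) in zip(idx, idx[1:]):
            if c2 - c1 <= 1:
                clustered.add((gene, i1))
                clustered.add((gene, i2))
    for gene, group in by_gene.items():
        for i, s in enumerate(group):
            if (gene, i) in clustered:
                dropped.append((s, CLUSTERED))
            else:
                kept.append(s)
    return kept, dropped


def write_dropped_report(dropped, path) -> None:
    """Write a dropped-site report TSV (gene, pos, reason)."""
    with open(path, "w") as fh:
        fh.write("gene\tpos\treason\n")
        for site, reason in dropped:
            fh.write(f"{site.gene_id}\t{site.pos}\t{reason}\n")


def write_sites_tsv(sites: Iterable[VariantSite], path) -> None:
    """Write sites as a variant TSV (gene, pos, ref, alt, level)."""
    with open(path, "w") as fh:
        fh.write("gene\tpos\tref\talt\tlevel\n")
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.pos}\t{s.ref_base}\t{s.alt_base}\t{s.level:.6g}\n"
            )
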