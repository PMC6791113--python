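"""Synthetic CDS sets, planted mutations, and read-allele tables.

The generator emulates the inputs of an RNA-seq-based polymorphism study
on coding sequences, so the whole pipeline can be exercised without any
download:

* ``simulate_cds`` writes gene models with tunable codon co-occurrence:
  each interior codon is, with probability ``pi_iso``, drawn uniformly
  from its predecessor's isoacceptor set (including the identical
  codon), with probability ``pi_noniso`` from the predecessor's
  nonisoaccepting synonymous codons, and otherwise uniformly from all
  61 sense codons.
* ``plant_mutations`` places biallelic single-base mutations with a
  context-conditional type composition and Beta-distributed allele
  levels rescaled into [0.02, 0.98], never putting two mutations in the
  same or adjacent codons.  Ground-truth labels are recorded by the
  generator's own labelling logic (it does not call the classifier).
* ``simulate_read_alleles`` draws multinomial read counts over the four
  two-site haplotypes, with a flat per-allele error rate.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codon_model import (
    STANDARD_CODE,
    STOP,
    AnticodonInventory,
    GeneticCode,
    IsoacceptorMap,
    build_isoacceptor_map,
)
from .io_ingest import CdsRecord, CdsSet

__all__ = [
    "SimConfig",
    "simulate_cds",
    "plant_mutations",
    "simulate_read_alleles",
    "make_fixture_bundle",
    "write_cds_fasta",
]

ISO = "ISOACCEPTING"
NONISO = "NONISO_SYNONYMOUS"
NONSYN = "NONSYNONYMOUS"
NONSENSE = "NONSENSE"
_TYPES = (ISO, NONISO, NONSYN, NONSENSE)

ISO_CTX = "ISO_CONTEXT"
NONISO_CTX = "NONISO_CONTEXT"
NONSYN_CTX = "NONSYN_CONTEXT"
_CONTEXTS = (ISO_CTX, NONISO_CTX, NONSYN_CTX)

_STOPS = ("TAA", "TAG", "TGA")

# Context-conditional mutation-type plan.  Probabilities are *requested*
# per target codon; achievability restriction (a codon with no single-base
# synonymous or nonsense change contributes none) renormalizes them, so
# the requested synonymous/nonsense shares are set above the study-like
# realized breakdown (~0.39 synonymous, ~0.016 nonsense).  Within
# synonymous, the iso fraction is 0.8 in an isoaccepting context and 0.4
# elsewhere (the planted enrichment); that conditional ratio is realized
# exactly (see plant_mutations).
_ENRICHED_PLAN = {
    ISO_CTX: {ISO: 0.512, NONISO: 0.128, NONSYN: 0.28, NONSENSE: 0.08},
    NONISO_CTX: {ISO: 0.256, NONISO: 0.384, NONSYN: 0.28, NONSENSE: 0.08},
    NONSYN_CTX: {ISO: 0.256, NONISO: 0.384, NONSYN: 0.28, NONSENSE: 0.08},
}

# A no-enrichment null: identical type composition in every context.
UNIFORM_PLAN = {
    ctx: {ISO: 0.256, NONISO: 0.384, NONSYN: 0.28, NONSENSE: 0.08}
    for ctx in _CONTEXTS
}


@dataclass
class SimConfig:
    """Parameters of a miniature synthetic study.

    Gene lengths are in codons including the ATG and the stop.  Beta
    parameters give the allele-level distribution per mutation class
    (rescaled into ``level_range``); the isoaccepting-in-isoaccepting-
    context synonymous group has its own, higher-mean Beta so the MAF
    shift the analysis looks for is planted by construction.
    """

    n_genes: int = 50
    mean_gene_length: int = 300
    length_distribution: str = "geometric"  # or "fixed"
    pi_iso: float = 0.15
    pi_noniso: float = 0.10
    plan: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {c: dict(_ENRICHED_PLAN[c]) for c in _CONTEXTS}
    )
    n_mutations: int = 500
    level_range: Tuple[float, float] = (0.02, 0.98)
    beta_iso_in_iso: Tuple[float, float] = (3.0, 7.0)   # mean 0.30
    beta_other_syn: Tuple[float, float] = (2.0, 8.0)    # mean 0.20
    beta_nonsyn: Tuple[float, float] = (1.9, 9.1)       # mean 0.19
    beta_nonsense: Tuple[float, float] = (1.4, 9.6)     # mean 0.14
    ld_haplotype_freqs: Tuple[float, float, float, float] = (0.5, 0.0, 0.0, 0.5)
    ld_depth: int = 200
    ld_error_rate: float = 0.005
    n_ld_pairs: int = 10
    iso_mode: str = "species"  # "species" (Zea mays fixture) or "all"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pi_iso <= 1.0 or not 0.0 <= self.pi_noniso <= 1.0:
            raise ValueError("pi_iso and pi_noniso must lie in [0, 1]")
        if self.pi_iso + self.pi_noniso > 1.0:
            raise ValueError("pi_iso + pi_noniso must not exceed 1")
        for ctx, row in self.plan.items():
            probs = [row.get(t, 0.0) for t in _TYPES]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"plan row for {ctx} must be a distribution")
        lo, hi = self.level_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("level_range must satisfy 0 < lo < hi < 1")

    def iso_map(self) -> IsoacceptorMap:
        if self.iso_mode == "species":
            return build_isoacceptor_map(AnticodonInventory.zea_mays())
        if self.iso_mode == "all":
            return build_isoacceptor_map(None)
        raise ValueError("iso_mode must be 'species' or 'all'")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_cds(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    iso_map: Optional[IsoacceptorMap] = None,
    code: GeneticCode = STANDARD_CODE,
) -> CdsSet:
    """Simulate a CDS set with tunable isoacceptor clustering.

    Each gene starts with ATG and ends with a uniformly chosen stop.
    A predecessor with an empty isoacceptor (or nonisoaccepting) set
    falls back to the identical codon on a clustered draw.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    iso_map = iso_map or config.iso_map()
    sense = sorted(code.sense_codons)
    iso_choices = {
        c: sorted(iso_map.isoacceptors[c] | {c}) for c in sense
    }
    by_aa: Dict[str, List[str]] = {}
    for c in sense:
        by_aa.setdefault(code.codon_to_amino_acid[c], []).append(c)
    noniso_choices = {
        c: sorted(
            set(by_aa[code.codon_to_amino_acid[c]])
            - iso_map.isoacceptors[c]
            - {c}
        )
        or [c]  # fall back to the identical codon
        for c in sense
    }

    records = {}
    for g in range(config.n_genes):
        if config.length_distribution == "fixed":
            n_codons = config.mean_gene_length
        elif config.length_distribution == "geometric":
            # interior length geometric with the requested mean
            interior_mean = max(config.mean_gene_length - 2, 1)
            n_codons = 2 + rng.geometric(1.0 / interior_mean)
        else:
            raise ValueError("length_distribution must be 'fixed' or 'geometric'")
        n_codons = max(n_codons, 3)
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            u = rng.random()
            prev = codons[-1]
            if u < config.pi_iso:
                pool = iso_choices[prev]
            elif u < config.pi_iso + config.pi_noniso:
                pool = noniso_choices[prev]
            else:
                pool = sense
            codons.append(pool[rng.integers(len(pool))])
        codons.append(_STOPS[rng.integers(3)])
        gene = f"g{g + 1:04d}"
        records[gene] = CdsRecord(
            gene_id=gene,
            transcript_id=f"{gene}_T001",
            sequence="".join(codons),
        )
    return CdsSet(records=records)


def write_cds_fasta(cds_set: CdsSet, path) -> None:
    """Write a CDS set as FASTA with Ensembl-plants style headers."""
    with open(path, "w") as fh:
        for gene in sorted(cds_set.records):
            rec = cds_set[gene]
            fh.write(f">{rec.transcript_id} cds gene:{rec.gene_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _label_variant(
    ref_codon: str, alt_codon: str, iso_map: IsoacceptorMap, code: GeneticCode
) -> str:
    """Generator-side mutation-type labelling (independent of classify)."""
    aa_ref = code.codon_to_amino_acid[ref_codon]
    aa_alt = code.codon_to_amino_acid[alt_codon]
    if aa_alt == STOP:
        return NONSENSE
    if aa_alt != aa_ref:
        return NONSYN
    return ISO if alt_codon in iso_map.isoacceptors[ref_codon] else NONISO


def _label_context(
    prev_codon: str, focal_codon: str, iso_map: IsoacceptorMap, code: GeneticCode
) -> str:
    aa_p = code.codon_to_amino_acid[prev_codon]
    aa_f = code.codon_to_amino_acid[focal_codon]
    if aa_p == STOP or aa_f == STOP:
        return NONSYN_CTX
    if prev_codon == focal_codon or focal_codon in iso_map.isoacceptors[prev_codon]:
        return ISO_CTX
    return NONISO_CTX if aa_p == aa_f else NONSYN_CTX


def _single_base_variants(codon: str) -> List[Tuple[int, str, str]]:
    """(offset, alt_base, alt_codon) for the codon's 9 single-base changes."""
    out = []
    for off in range(3):
        for b in "ACGT":
            if b != codon[off]:
                out.append((off, b, codon[:off] + b + codon[off + 1 :]))
    return out


def _level_params(config: SimConfig, mtype: str, context: str) -> Tuple[float, float]:
    if mtype == NONSENSE:
        return config.beta_nonsense
    if mtype == NONSYN:
        return config.beta_nonsyn
    if mtype == ISO and context == ISO_CTX:
        return config.beta_iso_in_iso
    return config.beta_other_syn


def plant_mutations(
    cds_set: CdsSet,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    iso_map: Optional[IsoacceptorMap] = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Plant biallelic mutations with a context-conditional type plan.

    Target codons are sampled uniformly over interior sense codons
    (never the first codon or the terminal stop), with the same-codon /
    adjacent-codon exclusion enforced by construction.  At each codon
    the plan is restricted to achievable types before drawing: if the
    isoaccepting and nonisoaccepting changes are not BOTH achievable,
    both are removed together (so the iso : noniso ratio conditional on
    a synonymous draw equals the plan ratio at every contributing
    codon); unachievable nonsense is removed; the row is renormalized.
    Codons with empty support are skipped and redrawn, up to a cap.

    Returns the ground-truth table: gene, pos, ref, alt, level,
    mutation_type, context_type.
    """
    config.validate()
    rng = _rng(config.seed + 1 if rng is None else rng)
    iso_map = iso_map or config.iso_map()

    candidates: List[Tuple[str, int]] = []  # (gene, 0-based codon index)
    for cds in cds_set:
        nc = cds.n_codons
        candidates.extend((cds.gene_id, ci) for ci in range(1, nc - 1))
    if not candidates:
        raise ValueError("no interior codons available for planting")

    occupied: Dict[str, set] = {}
    rows = []
    lo, hi = config.level_range
    n_skipped = 0
    max_draws = 200 * config.n_mutations
    draws = 0
    while len(rows) < config.n_mutations and draws < max_draws:
        draws += 1
        gene, ci = candidates[rng.integers(len(candidates))]
        occ = occupied.setdefault(gene, set())
        if {ci - 1, ci, ci + 1} & occ:
            continue
        cds = cds_set[gene]
        focal = cds.codon(ci + 1)  # codon() is 1-based
        prev = cds.codon(ci)
        if (
            "N" in focal
            or "N" in prev
            or code.codon_to_amino_acid.get(focal) in (None, STOP)
        ):
            n_skipped += 1
            continue
        context = _label_context(prev, focal, iso_map, code)

        variants = _single_base_variants(focal)
        by_type: Dict[str, List[Tuple[int, str, str]]] = {t: [] for t in _TYPES}
        for off, alt_base, alt_codon in variants:
            by_type[_label_variant(focal, alt_codon, iso_map, code)].append(
                (off, alt_base, alt_codon)
            )

        probs = dict(config.plan[context])
        if not (by_type[ISO] and by_type[NONISO]):
            probs[ISO] = 0.0
            probs[NONISO] = 0.0
        if not by_type[NONSENSE]:
            probs[NONSENSE] = 0.0
        total = sum(probs.get(t, 0.0) for t in _TYPES)
        if total <= 0:
            n_skipped += 1
            continue
        p = np.array([probs.get(t, 0.0) for t in _TYPES]) / total
        mtype = _TYPES[rng.choice(len(_TYPES), p=p)]
        options = by_type[mtype]
        off, alt_base, _alt = options[rng.integers(len(options))]

        a, b = _level_params(config, mtype, context)
        level = lo + (hi - lo) * rng.beta(a, b)
        rows.append(
            {
                "gene": gene,
                "pos": ci * 3 + off + 1,
                "ref": focal[off],
                "alt": alt_base,
                "level": level,
                "mutation_type": mtype,
                "context_type": context,
            }
        )
        occ.add(ci)
    if len(rows) < config.n_mutations:
        warnings.warn(
            f"planted only {len(rows)}/{config.n_mutations} mutations "
            f"(draw cap reached; {n_skipped} codons had empty plan support)",
            stacklevel=2,
        )
    truth = pd.DataFrame(rows).sort_values(["gene", "pos"]).reset_index(drop=True)
    return truth


def simulate_read_alleles(
    haplotype_freqs: Sequence[float],
    depth: int,
    error_rate: float,
    seed_or_rng,
    sites: Optional[Tuple[Tuple[str, str, str], Tuple[str, str, str]]] = None,
) -> pd.DataFrame:
    """Multinomial reads over (RR, RM, MR, MM) for one site pair.

    ``sites`` gives ((site_id, ref, alt), (site_id, ref, alt)); by
    default a generic pair ``ld_g1:10`` / ``ld_g1:40`` with A/G and C/T
    alleles.  Each observed allele is independently flipped to a random
    other base with probability ``error_rate``.
    """
    freqs = np.asarray(haplotype_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("haplotype_freqs must be 4 non-negative values summing to 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed_or_rng)
    if sites is None:
        sites = (("ld_g1:10", "A", "G"), ("ld_g1:40", "C", "T"))
    (id1, ref1, alt1), (id2, ref2, alt2) = sites
    counts = rng.multinomial(depth, freqs)
    haplos = [(ref1, ref2), (ref1, alt2), (alt1, ref2), (alt1, alt2)]

    rows = []
    read_no = 0
    bases = "ACGT"
    for (b1, b2), k in zip(haplos, counts):
        for _ in range(k):
            read_no += 1
            rid = f"r{read_no:06d}"
            for sid, b in ((id1, b1), (id2, b2)):
                if error_rate > 0 and rng.random() < error_rate:
                    others = [x for x in bases if x != b]
                    b = others[rng.integers(3)]
                rows.append({"read_id": rid, "site_id": sid, "base": b})
    return pd.DataFrame(rows, columns=["read_id", "site_id", "base"])


def make_fixture_bundle(config: SimConfig, out_dir) -> Dict[str, object]:
    """Generate a complete miniature study in ``out_dir``.

    Writes ``cds.fa`` (simulated genes), ``variants.tsv`` (the pipeline
    input: gene, pos, ref, alt, level), ``truth.tsv`` (with the planted
    type and context labels), ``ld_reads.tsv`` + ``ld_sites.tsv`` (per-
    read alleles for ``n_ld_pairs`` site pairs) and ``params.txt``.
    Returns the in-memory objects alongside the paths.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iso_map = config.iso_map()
    rng = _rng(config.seed)

    cds_set = simulate_cds(config, rng=rng, iso_map=iso_map)
    write_cds_fasta(cds_set, out / "cds.fa")

    truth = plant_mutations(cds_set, config, rng=rng, iso_map=iso_map)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    truth[["gene", "pos", "ref", "alt", "level"]].to_csv(
        out / "variants.tsv", sep="\t", index=False
    )

    ld_frames = []
    ld_sites = []
    for i in range(config.n_ld_pairs):
        pair_sites = (
            (f"ld_g{i + 1}:10", "A", "G"),
            (f"ld_g{i + 1}:40", "C", "T"),
        )
        ld_frames.append(
            simulate_read_alleles(
                config.ld_haplotype_freqs,
                config.ld_depth,
                config.ld_error_rate,
                rng,
                sites=pair_sites,
            )
        )
        for sid, ref, alt in pair_sites:
            gene, pos = sid.split(":")
            ld_sites.append({"gene": gene, "pos": int(pos), "ref": ref, "alt": alt})
    ld_reads = pd.concat(ld_frames, ignore_index=True)
    ld_reads.to_csv(out / "ld_reads.tsv", sep="\t", index=False)
    pd.DataFrame(ld_sites).to_csv(out / "ld_sites.tsv", sep="\t", index=False)

    with open(out / "params.txt", "w") as fh:
        fh.write("planted synthetic study parameters\n")
        for key, val in vars(config).items():
            fh.write(f"{key} = {val!r}\n")

    return {
        "cds_set": cds_set,
        "truth": truth,
        "ld_reads": ld_reads,
        "ld_sites": ld_sites,
        "paths": {
            "cds": out / "cds.fa",
            "variants": out / "variants.tsv",
            "truth": out / "truth.tsv",
            "ld_reads": out / "ld_reads.tsv",
            "ld_sites": out / "ld_sites.tsv",
        },
    }
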