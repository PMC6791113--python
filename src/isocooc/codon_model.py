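"""Genetic code, wobble decoding, and isoacceptor relationships.

Two synonymous codons are *isoaccepting* when at least one tRNA anticodon
can decode both of them.  Which anticodons exist differs between species
(some wobble anticodons are simply absent from a genome's tRNA gene set),
so the isoacceptor relation comes in two flavours:

* ``ALL_POSSIBLE`` — every anticodon admissible under the wobble rules is
  assumed present.
* ``SPECIES`` — the admissible anticodons are intersected with a species
  tRNA inventory (GtRNAdb-style amino-acid/anticodon table).

Wobble pairing model (anticodon position 34 against the codon's third
base; positions 35/36 pair strict Watson–Crick):

====  ==================
 34    codon third base
====  ==================
 G     C, T
 C     G
 U     A, G
 A     T, C, A   (A34 is read as inosine)
====  ==================

An anticodon is *admissible* only if every codon it decodes is a sense
codon for one and the same amino acid; e.g. an A34 anticodon in the TTN
box would span Phe and Leu and is excluded from the universe.

Codons are DNA strings (T, not U); anticodons are written 5'→3' with U
(so the wobble base comes first) but T is accepted on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from itertools import product
from typing import FrozenSet, Iterable, Mapping, Optional

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "STOP",
    "GeneticCode",
    "STANDARD_CODE",
    "AnticodonInventory",
    "IsoacceptorMap",
    "Relation",
    "translate",
    "decoded_codons",
    "decoding_anticodons",
    "build_isoacceptor_map",
    "codon_relationship",
    "read_trna_inventory",
]

STOP = "*"

_BASES = "ACGT"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
# anticodon position 34 (5' base) -> codon third bases it pairs with
_WOBBLE_34 = {
    "G": frozenset("CT"),
    "C": frozenset("G"),
    "T": frozenset("AG"),   # U34
    "A": frozenset("TCA"),  # A34 read as inosine
}

_AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


class InvalidCodonError(ValueError):
    """Raised for strings that are not 3-base ACGT codons."""


class Relation(str, Enum):
    """Relationship between two codons."""

    ISOACCEPTING = "ISOACCEPTING"
    NONISO_SYNONYMOUS = "NONISO_SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"


def _to_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def _to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid table (1-letter symbols, ``*`` for stop)."""

    codon_to_amino_acid: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_amino_acid) != 64:
            raise ValueError("genetic code must cover all 64 codons")
        stops = [c for c, a in self.codon_to_amino_acid.items() if a == STOP]
        if len(stops) != 3:
            raise ValueError("expected exactly 3 stop codons")

    @property
    def sense_codons(self) -> FrozenSet[str]:
        return frozenset(
            c for c, a in self.codon_to_amino_acid.items() if a != STOP
        )

    @property
    def stop_codons(self) -> FrozenSet[str]:
        return frozenset(
            c for c, a in self.codon_to_amino_acid.items() if a == STOP
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = dict(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            table[c] = STOP
        return cls(codon_to_amino_acid=table)


STANDARD_CODE = GeneticCode.standard()


def _check_codon(codon: str) -> str:
    codon = _to_dna(codon)
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise InvalidCodonError(f"not a valid ACGT codon: {codon!r}")
    return codon


def translate(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a DNA codon to its 1-letter amino acid, ``*`` for stop."""
    return code.codon_to_amino_acid[_check_codon(codon)]


def decoded_codons(anticodon: str) -> FrozenSet[str]:
    """All codons a 5'→3' anticodon decodes under the wobble rules."""
    ac = _check_codon(anticodon)  # same alphabet checks apply
    first = _WC[ac[2]]
    second = _WC[ac[1]]
    return frozenset(first + second + third for third in _WOBBLE_34[ac[0]])


def _is_admissible(anticodon_dna: str, code: GeneticCode) -> bool:
    aas = {code.codon_to_amino_acid[c] for c in decoded_codons(anticodon_dna)}
    return len(aas) == 1 and STOP not in aas


def admissible_anticodons(code: GeneticCode = STANDARD_CODE) -> FrozenSet[str]:
    """The universe of anticodons whose decoded codons are synonymous.

    Returned 5'→3' in the RNA alphabet (U).
    """
    return frozenset(
        _to_rna("".join(p))
        for p in product(_BASES, repeat=3)
        if _is_admissible("".join(p), code)
    )


@dataclass(frozen=True)
class AnticodonInventory:
    """A species' tRNA anticodon repertoire.

    ``entries`` holds (1-letter amino acid, anticodon 5'→3' RNA) pairs.
    """

    entries: FrozenSet[tuple]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for aa, ac in self.entries:
            if len(_to_dna(ac)) != 3:
                raise ValueError(f"anticodon must be 3 bases: {ac!r}")
            if (aa, ac) in seen:
                raise ValueError(f"duplicate inventory entry: {(aa, ac)}")
            seen.add((aa, ac))

    @property
    def anticodons(self) -> FrozenSet[str]:
        return frozenset(_to_rna(ac) for _, ac in self.entries)

    def validated_anticodons(
        self, code: GeneticCode = STANDARD_CODE
    ) -> FrozenSet[str]:
        """Anticodons after dropping inadmissible or mislabelled entries.

        An entry whose anticodon decodes codons of more than one amino
        acid (or a stop), or whose declared amino acid disagrees with the
        decoded one, is excluded with a warning.
        """
        keep = set()
        for aa, ac in sorted(self.entries):
            ac_rna = _to_rna(ac)
            ac_dna = _to_dna(ac)
            if not _is_admissible(ac_dna, code):
                warnings.warn(
                    f"anticodon {ac_rna} ({aa}) decodes codons of mixed "
                    "amino acids; excluded from the isoacceptor model",
                    stacklevel=2,
                )
                continue
            decoded_aa = code.codon_to_amino_acid[
                next(iter(decoded_codons(ac_dna)))
            ]
            if decoded_aa != aa:
                warnings.warn(
                    f"anticodon {ac_rna} declared {aa} but decodes "
                    f"{decoded_aa}; excluded",
                    stacklevel=2,
                )
                continue
            keep.add(ac_rna)
        return frozenset(keep)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple], source_label: str = ""
    ) -> "AnticodonInventory":
        return cls(
            entries=frozenset((aa, _to_rna(ac)) for aa, ac in pairs),
            source_label=source_label,
        )

    @classmethod
    def full(cls) -> "AnticodonInventory":
        """The shipped FULL fixture: every admissible anticodon."""
        return _load_fixture("full_anticodons.tsv", "FULL")

    @classmethod
    def zea_mays(cls) -> "AnticodonInventory":
        """The shipped Zea mays fixture: FULL minus the Gly A34 anticodon."""
        return _load_fixture("zea_mays_anticodons.tsv", "ZEA_MAYS")


def read_trna_inventory(path, source_label: str = "") -> AnticodonInventory:
    """Read a GtRNAdb-style tab-separated tRNA inventory.

    Columns: amino_acid (1- or 3-letter), anticodon (5'→3', T or U),
    gene_count.  A header line is detected and skipped.  Rows with
    gene_count < 1 are ignored (the anticodon is absent from the genome).
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            aa, ac, count = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if lineno == 1 and not count.lstrip("-").isdigit():
                continue  # header
            aa = _AA_3TO1.get(aa, aa)
            if int(count) >= 1:
                pairs.append((aa, ac))
    return AnticodonInventory.from_pairs(pairs, source_label or str(path))


def _load_fixture(name: str, label: str) -> AnticodonInventory:
    ref = resources.files("isocooc.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_trna_inventory(path, source_label=label)


def _wobble_anticodons(codon: str, code: GeneticCode) -> FrozenSet[str]:
    """Admissible anticodons pairing a sense codon under the wobble rules."""
    hits = set()
    for b34 in _BASES:
        ac_dna = b34 + _WC[codon[1]] + _WC[codon[0]]
        if codon[2] in _WOBBLE_34[b34] and _is_admissible(ac_dna, code):
            hits.add(_to_rna(ac_dna))
    return frozenset(hits)


def decoding_anticodons(
    codon: str,
    inventory: Optional[AnticodonInventory] = None,
    code: GeneticCode = STANDARD_CODE,
) -> FrozenSet[str]:
    """Anticodons (5'→3', RNA) that can decode a sense codon.

    With ``inventory=None`` (ALL_POSSIBLE mode) the result is every
    admissible anticodon pairing the codon; with an inventory the result
    is further intersected with the species' validated anticodon set.
    An empty set is a valid result.
    """
    codon = _check_codon(codon)
    if code.codon_to_amino_acid[codon] == STOP:
        raise InvalidCodonError(f"stop codon {codon} has no decoding tRNA")
    hits = _wobble_anticodons(codon, code)
    if inventory is not None:
        hits &= inventory.validated_anticodons(code)
    return frozenset(hits)


@dataclass(frozen=True)
class IsoacceptorMap:
    """Per-codon decoding anticodons and isoaccepting partner codons.

    ``isoacceptors[c]`` is the set of codons *other than c* that are
    synonymous with c and share at least one decoding anticodon with it.
    ``mode`` is ``"ALL_POSSIBLE"`` or ``"SPECIES"``.
    """

    decoding_anticodons: Mapping[str, FrozenSet[str]]
    isoacceptors: Mapping[str, FrozenSet[str]]
    mode: str
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def iso(self, codon: str) -> FrozenSet[str]:
        return self.isoacceptors[_check_codon(codon)]


def build_isoacceptor_map(
    inventory: Optional[AnticodonInventory] = None,
    code: GeneticCode = STANDARD_CODE,
) -> IsoacceptorMap:
    """Build the isoacceptor relation over all 61 sense codons.

    ``inventory=None`` gives the ALL_POSSIBLE map; an inventory gives the
    SPECIES map (the relation can only shrink under restriction).
    """
    valid = inventory.validated_anticodons(code) if inventory is not None else None
    dec = {}
    for c in code.sense_codons:
        hits = _wobble_anticodons(c, code)
        dec[c] = hits & valid if valid is not None else hits
    by_aa: dict = {}
    for c in code.sense_codons:
        by_aa.setdefault(code.codon_to_amino_acid[c], []).append(c)
    iso = {}
    for c in code.sense_codons:
        partners = frozenset(
            c2
            for c2 in by_aa[code.codon_to_amino_acid[c]]
            if c2 != c and dec[c] & dec[c2]
        )
        iso[c] = partners
    mode = "ALL_POSSIBLE" if inventory is None else "SPECIES"
    return IsoacceptorMap(
        decoding_anticodons=dec, isoacceptors=iso, mode=mode, code=code
    )


def codon_relationship(
    c1: str,
    c2: str,
    iso_map: IsoacceptorMap,
    code: GeneticCode = STANDARD_CODE,
) -> Relation:
    """Classify the relation between two codons.

    Identical sense codons are ISOACCEPTING (they trivially share every
    tRNA).  Stop codons have no isoacceptors: any pair involving a stop
    codon is NONSYNONYMOUS.
    """
    c1, c2 = _check_codon(c1), _check_codon(c2)
    a1 = code.codon_to_amino_acid[c1]
    a2 = code.codon_to_amino_acid[c2]
    if a1 == STOP or a2 == STOP:
        return Relation.NONSYNONYMOUS
    if c1 == c2:
        return Relation.ISOACCEPTING
    if a1 != a2:
        return Relation.NONSYNONYMOUS
    if c2 in iso_map.isoacceptors[c1]:
        return Relation.ISOACCEPTING
    return Relation.NONISO_SYNONYMOUS
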