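"""Shared fixtures: isoacceptor maps and the frozen isoacceptor table.

The table below is the published per-codon isoacceptor listing for the
59 sense codons (excluding ATG, TGG and stops): columns are codon, the
isoacceptors when every admissible wobble anticodon exists, and the
Zea mays column (which lacks the Gly inosine anticodon).  It was frozen
here by hand and serves as the oracle the codon model is checked
against — the implementation derives the relation from wobble rules and
never reads this table.
"""

import pytest
from hypothesis import settings

from isocooc import AnticodonInventory, build_isoacceptor_map

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

ISOACCEPTOR_TABLE = """\
AAA AAG AAG
AAC AAT AAT
AAG AAA AAA
AAT AAC AAC
ACA ACC/ACT/ACG ACC/ACT/ACG
ACC ACA/ACT ACA/ACT
ACG ACA ACA
ACT ACA/ACC ACA/ACC
AGA AGG AGG
AGC AGT AGT
AGG AGA AGA
AGT AGC AGC
ATA ATT/ATC ATT/ATC
ATC ATA/ATT ATA/ATT
ATT ATA/ATC ATA/ATC
CAA CAG CAG
CAC CAT CAT
CAG CAA CAA
CAT CAC CAC
CCA CCC/CCT/CCG CCC/CCT/CCG
CCC CCA/CCT CCA/CCT
CCG CCA CCA
CCT CCC/CCA CCC/CCA
CGA CGC/CGT/CGG CGC/CGT/CGG
CGC CGA/CGT CGA/CGT
CGG CGA CGA
CGT CGC/CGA CGC/CGA
CTA CTT/CTC/CTG CTT/CTC/CTG
CTC CTA/CTT CTA/CTT
CTG CTA CTA
CTT CTA/CTC CTA/CTC
GAA GAG GAG
GAC GAT GAT
GAG GAA GAA
GAT GAC GAC
GCA GCT/GCC/GCG GCT/GCC/GCG
GCC GCT/GCA GCT/GCA
GCG GCA GCA
GCT GCA/GCC GCA/GCC
GGA GGC/GGT/GGG GGG
GGC GGA/GGT GGT
GGG GGA GGA
GGT GGC/GGA GGC
GTA GTC/GTT/GTG GTC/GTT/GTG
GTC GTT/GTA GTT/GTA
GTG GTA GTA
GTT GTC/GTA GTC/GTA
TAC TAT TAT
TAT TAC TAC
TCA TCC/TCT/TCG TCC/TCT/TCG
TCC TCA/TCT TCA/TCT
TCG TCA TCA
TCT TCA/TCC TCA/TCC
TGC TGT TGT
TGT TGC TGC
TTA TTG TTG
TTC TTT TTT
TTG TTA TTA
TTT TTC TTC
"""


def isoacceptor_table_rows():
    """(codon, all-possible set, Zea mays set) for all 59 listed codons."""
    rows = []
    for line in ISOACCEPTOR_TABLE.strip().splitlines():
        codon, all_col, zea_col = line.split()
        rows.append((codon, frozenset(all_col.split("/")), frozenset(zea_col.split("/"))))
    assert len(rows) == 59
    return rows


@pytest.fixture(scope="session")
def table_rows():
    return isoacceptor_table_rows()


@pytest.fixture(scope="session")
def all_map():
    return build_isoacceptor_map(None)


@pytest.fixture(scope="session")
def zea_map():
    return build_isoacceptor_map(AnticodonInventory.zea_mays())
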