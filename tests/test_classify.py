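"""Mutation/context classification, the genome census, and CpG handling."""

import pytest
from hypothesis import given, strategies as st

from isocooc import (
    CdsRecord,
    CdsSet,
    ContextType,
    MutationType,
    VariantSite,
    classified_to_frame,
    classify_context,
    classify_mutation,
    classify_mutations,
    cpg_annotate,
    cpg_content,
    genome_context_census,
    translate,
)
from tests.conftest import isoacceptor_table_rows

_TABLE_ALL = {c: s for c, s, _ in isoacceptor_table_rows()}
_TABLE_ZEA = {c: s for c, _, s in isoacceptor_table_rows()}


def oracle_relation(prev, cur, zea=False):
    """Independent codon-pair classifier from the frozen published table."""
    if translate(prev) == "*" or translate(cur) == "*":
        return "NONSYN"
    if translate(prev) != translate(cur):
        return "NONSYN"
    if prev == cur:
        return "ISO"
    table = _TABLE_ZEA if zea else _TABLE_ALL
    return "ISO" if cur in table.get(prev, frozenset()) else "NONISO"


def cds_set(**genes):
    return CdsSet(
        records={
            g: CdsRecord(gene_id=g, transcript_id=f"{g}_T001", sequence=s)
            for g, s in genes.items()
        }
    )


def site(gene, pos, ref, alt, level=0.3):
    return VariantSite(gene, pos, ref, alt, level)


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "seq,pos,ref,alt,which,expected",
        [
            # AAA -> AAG: still decoded by the Lys U34 anticodon
            ("ATGAAATGA", 6, "A", "G", "zea", MutationType.ISOACCEPTING),
            # GGA -> GGT: Zea mays lacks the Gly inosine anticodon
            ("ATGGGATGA", 6, "A", "T", "zea", MutationType.NONISO_SYNONYMOUS),
            ("ATGGGATGA", 6, "A", "T", "all", MutationType.ISOACCEPTING),
            # TGC -> TGA: stop gain
            ("ATGTGCTGA", 6, "C", "A", "zea", MutationType.NONSENSE),
            # GGA -> AGA: Gly -> Arg
            ("ATGGGATGA", 4, "G", "A", "zea", MutationType.NONSYNONYMOUS),
            # inside the terminal stop codon
            ("ATGGGATGA", 9, "A", "G", "zea", MutationType.STOP_LOSS),
        ],
    )
    def test_types(self, seq, pos, ref, alt, which, expected, all_map, zea_map):
        m = all_map if which == "all" else zea_map
        cds = CdsRecord("g1", "g1_T001", seq)
        assert classify_mutation(site("g1", pos, ref, alt), cds, m) is expected

    def test_ref_base_mismatch_raises(self, zea_map):
        cds = CdsRecord("g1", "g1_T001", "ATGAAATGA")
        with pytest.raises(ValueError, match="ref base"):
            classify_mutation(site("g1", 6, "C", "G"), cds, zea_map)


class TestClassifyContext:
    def test_iso_context(self, zea_map):
        cds = CdsRecord("g1", "g1_T001", "ATGAAAAAGTGA")  # prev AAA, focal AAG
        assert (
            classify_context(site("g1", 9, "G", "A"), cds, zea_map)
            is ContextType.ISO_CONTEXT
        )

    def test_noniso_context_zea_mays(self, zea_map):
        cds = CdsRecord("g1", "g1_T001", "ATGGGTGGATGA")  # prev GGT, focal GGA
        assert (
            classify_context(site("g1", 9, "A", "G"), cds, zea_map)
            is ContextType.NONISO_CONTEXT
        )

    def test_first_codon_has_no_context(self, zea_map):
        cds = CdsRecord("g1", "g1_T001", "ATGAAATGA")
        assert (
            classify_context(site("g1", 1, "A", "G"), cds, zea_map)
            is ContextType.NO_CONTEXT
        )

    def test_polymorphic_previous_codon_excluded(self, zea_map):
        cds = CdsRecord("g1", "g1_T001", "ATGAAAAAGTGA")
        ctx = classify_context(
            site("g1", 9, "G", "A"), cds, zea_map, polymorphic_codons={("g1", 2)}
        )
        assert ctx is ContextType.EXCLUDED_POLYMORPHIC_CONTEXT

    def test_alt_focal_flag_switches_focal_codon(self, zea_map):
        # prev AAA; focal ref AAT (Asn, nonsyn ctx) -> alt AAG (iso ctx)
        cds = CdsRecord("g1", "g1_T001", "ATGAAAAATTGA")
        s = site("g1", 9, "T", "G")
        assert classify_context(s, cds, zea_map) is ContextType.NONSYN_CONTEXT
        assert (
            classify_context(s, cds, zea_map, use_alt_focal=True)
            is ContextType.ISO_CONTEXT
        )


class TestGenomeCensus:
    def test_hand_enumerated_single_gene(self, zea_map):
        cen = genome_context_census(cds_set(g1="ATGAAAAAGTGA"), zea_map)
        assert (cen.n_codons, cen.n_iso, cen.n_noniso, cen.n_nonsyn) == (4, 1, 0, 2)
        assert cen.identity_holds

    def test_hand_enumerated_zea_mays_noniso(self, zea_map):
        cen = genome_context_census(cds_set(g1="ATGGGAGGTTGA"), zea_map)
        assert (cen.n_iso, cen.n_noniso, cen.n_nonsyn) == (0, 1, 2)

    def test_single_codon_gene(self, zea_map):
        cen = genome_context_census(cds_set(g1="ATG"), zea_map)
        assert cen.n_codons == 1 and cen.n_iso == cen.n_noniso == cen.n_nonsyn == 0
        assert cen.identity_holds

    def test_ambiguous_codons_counted_separately(self, zea_map):
        cen = genome_context_census(cds_set(g1="ATGANAAAGTGA"), zea_map)
        assert cen.n_ambiguous == 2  # both pairs touching the N codon
        assert cen.identity_holds

    @given(
        gene_codons=st.lists(
            st.lists(
                st.sampled_from(sorted(_TABLE_ALL) + ["ATG", "TGG", "TAA", "TGA"]),
                min_size=1,
                max_size=12,
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_census_matches_pairwise_oracle_and_identity(self, zea_map, gene_codons):
        genes = {
            f"g{i}": "".join(codons) for i, codons in enumerate(gene_codons)
        }
        cen = genome_context_census(cds_set(**genes), zea_map)
        exp = {"ISO": 0, "NONISO": 0, "NONSYN": 0}
        for codons in gene_codons:
            for prev, cur in zip(codons, codons[1:]):
                exp[oracle_relation(prev, cur, zea=True)] += 1
        assert (cen.n_iso, cen.n_noniso, cen.n_nonsyn) == (
            exp["ISO"],
            exp["NONISO"],
            exp["NONSYN"],
        )
        assert cen.identity_holds


class TestCpg:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [
            ("ACGT", 2, True),   # C followed by G
            ("ACGT", 3, True),   # G preceded by C
            ("ACGT", 1, False),
            ("ACGT", 4, False),
            ("ATTA", 2, False),
            ("CGTA", 1, True),   # sequence edge: only right neighbour exists
        ],
    )
    def test_in_cpg(self, seq, pos, expected):
        cds = cds_set(g1=seq)
        assert cpg_annotate([site("g1", pos, seq[pos - 1], "A" if seq[pos-1] != "A" else "T")], cds) == [expected]

    @pytest.mark.parametrize(
        "seq,observed,expected",
        [
            ("CGCG", 2 / 3, 0.25),
            ("ATAT", 0.0, 0.0),
            ("CCGG", 1 / 3, 0.25),
        ],
    )
    def test_cpg_content(self, seq, observed, expected):
        obs, exp = cpg_content(cds_set(g1=seq))
        assert obs == pytest.approx(observed)
        assert exp == pytest.approx(expected)

    def test_cpg_content_empty_raises(self):
        with pytest.raises(ValueError):
            cpg_content(cds_set())


class TestClassifyMutations:
    def test_stop_loss_sites_excluded_from_tally(self, zea_map):
        cds = cds_set(g1="ATGGGATGA")
        out = classify_mutations([site("g1", 9, "A", "G")], cds, zea_map)
        assert out == []

    def test_frame_has_one_row_per_site_with_both_labels(self, zea_map):
        cds = cds_set(g1="ATGAAAAAGTGA", g2="ATGGGATGA")
        sites = [site("g1", 9, "G", "A"), site("g2", 6, "A", "T")]
        frame = classified_to_frame(classify_mutations(sites, cds, zea_map))
        assert len(frame) == 2
        assert set(frame.columns) >= {"mutation_type", "context_type", "maf", "in_cpg"}
        assert frame["mutation_type"].notna().all()
        assert frame["context_type"].notna().all()
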