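"""I/O layer: tree labelling, table parsing, proteome preparation, SNP
context assignment, TPM conversion and ORF extraction."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genebirth import phylo_io
from genebirth.phylo_io import (
    GeneRecord,
    counts_to_tpm,
    extract_orfs,
    parse_duplications,
    parse_orthogroups,
    parse_snps,
    parse_species_tree,
    prepare_proteome,
)

# --------------------------------------------------------------------------
# species tree
# --------------------------------------------------------------------------


class TestSpeciesTree:
    def test_yeast_tree_reference_path_labels(self, yeast_tree):
        assert yeast_tree.labels == ["N0", "N1", "N2", "N3", "N4", "N5"]
        assert yeast_tree.branch_length("N0") == pytest.approx(0.043)

    def test_two_tip_tree_labels(self):
        tree = parse_species_tree("(ref:0.1,other:0.2);", "ref")
        assert tree.labels == ["N0", "N1"]
        assert tree.mrca_label({"ref"}) == "N0"
        assert tree.mrca_label({"ref", "other"}) == "N1"

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            parse_species_tree("(a:1,b:1);", "zz")

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError):
            parse_species_tree("((a:1,b:1;", "a")

    def test_roundtrip_preserves_labels_and_lengths(self, yeast_tree):
        again = parse_species_tree(yeast_tree.to_newick(), "S_cerevisiae")
        assert again.labels == yeast_tree.labels
        for lab in yeast_tree.labels:
            assert again.branch_length(lab) == pytest.approx(
                yeast_tree.branch_length(lab)
            )

    def test_tip_group_member_counts_as_tip(self, flies_tree):
        # D_paulistorum shares the D_willistoni terminal node
        label = flies_tree.mrca_label({"D_melanogaster", "D_paulistorum"})
        assert label == flies_tree.mrca_label({"D_melanogaster", "D_willistoni"})

    def test_unknown_species_raises(self, yeast_tree):
        with pytest.raises(ValueError, match="not in tree"):
            yeast_tree.mrca_label({"S_cerevisiae", "H_sapiens"})


# --------------------------------------------------------------------------
# orthogroups and duplications
# --------------------------------------------------------------------------


class TestTables:
    OG = "Orthogroup\tspA\tspB\nOG1\tg1, g2\tg3\nOG2\tg4\t\n"

    def test_parse_orthogroups(self):
        ogs = parse_orthogroups(io.StringIO(self.OG))
        assert ogs[0].members == {"spA": ("g1", "g2"), "spB": ("g3",)}
        assert "spB" not in ogs[1].members  # empty cell omitted

    def test_duplicate_gene_raises(self):
        text = "Orthogroup\tspA\nOG1\tg1\nOG2\tg1\n"
        with pytest.raises(ValueError, match="g1"):
            parse_orthogroups(io.StringIO(text))

    def test_orthogroup_roundtrip(self, tmp_path):
        ogs = parse_orthogroups(io.StringIO(self.OG))
        path = tmp_path / "og.tsv"
        phylo_io.write_orthogroups(ogs, path)
        assert parse_orthogroups(path) == ogs

    DUP = (
        "Orthogroup\tSpecies Tree Node\tSupport\tGenes 1\tGenes 2\n"
        "OG1\tN1\t0.9\tg1\tg2, g3\n"
        "OG1\tN0\t1.0\tg1\tg4\n"
    )

    def test_parse_duplications(self, yeast_tree):
        recs = parse_duplications(io.StringIO(self.DUP), tree=yeast_tree)
        assert recs[0].species_tree_node == "N1"
        assert recs[0].support == pytest.approx(0.9)
        assert recs[0].genes_2 == ("g2", "g3")
        assert recs[1].support == 1.0

    def test_missing_genes2_raises(self):
        text = "Orthogroup\tSpecies Tree Node\tSupport\tGenes 1\tGenes 2\nOG1\tN1\t0.9\tg1\t\n"
        with pytest.raises(ValueError, match="Genes 2"):
            parse_duplications(io.StringIO(text))

    def test_unknown_node_raises(self, yeast_tree):
        text = "Orthogroup\tSpecies Tree Node\tSupport\tGenes 1\tGenes 2\nOG1\tN99\t0.9\tg1\tg2\n"
        with pytest.raises(ValueError, match="N99"):
            parse_duplications(io.StringIO(text), tree=yeast_tree)

    def test_duplication_roundtrip(self, tmp_path):
        recs = parse_duplications(io.StringIO(self.DUP))
        path = tmp_path / "dup.tsv"
        phylo_io.write_duplications(recs, path)
        assert parse_duplications(path) == recs


# --------------------------------------------------------------------------
# proteome preparation
# --------------------------------------------------------------------------


def _gene(gene_id, start, end, cds, strand="+", contig="chr1", isoform=None):
    return GeneRecord(
        gene_id=gene_id,
        species="sp",
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        cds_na=cds,
        isoform_id=isoform,
    )


CLEAN_30 = "ATG" + "GCT" * 28 + "TAA"  # 29-aa protein
CLEAN_12 = "ATG" + "GCT" * 10 + "TAA"  # 11-aa protein


class TestPrepareProteome:
    def test_longest_isoform_kept(self):
        isoforms = [
            _gene("g1", 0, 90, CLEAN_30, isoform="t1"),
            _gene("g1", 0, 36, CLEAN_12, isoform="t2"),
        ]
        kept = prepare_proteome(isoforms)
        assert len(kept) == 1 and kept[0].isoform_id == "t1"

    def test_equal_length_tie_breaks_lexicographically(self):
        isoforms = [
            _gene("g1", 0, 36, CLEAN_12, isoform="tB"),
            _gene("g1", 0, 36, CLEAN_12, isoform="tA"),
        ]
        assert prepare_proteome(isoforms)[0].isoform_id == "tA"

    def test_internal_stop_discarded(self):
        assert prepare_proteome([_gene("g1", 0, 12, "ATGTAAAAATGA")]) == []

    def test_non_atg_start_discarded(self):
        assert prepare_proteome([_gene("g1", 0, 9, "CTGAAATAA")]) == []

    def test_overlap_rule_is_asymmetric(self):
        # P (100 bp) overlaps Q (1000 bp) by 20 bp on the same strand:
        # 20/100 > 10% removes P; 20/1000 <= 10% keeps Q
        p = _gene("p", 980, 1080, CLEAN_30)
        q = _gene("q", 0, 1000, CLEAN_30)
        kept = prepare_proteome([p, q])
        assert [g.gene_id for g in kept] == ["q"]

    def test_opposite_strand_overlap_ignored(self):
        p = _gene("p", 980, 1080, CLEAN_30, strand="-")
        q = _gene("q", 0, 1000, CLEAN_30)
        assert len(prepare_proteome([p, q])) == 2

    def test_idempotent(self):
        genes = [
            _gene("a", 0, 100, CLEAN_30),
            _gene("b", 50, 160, CLEAN_30),
            _gene("c", 300, 400, CLEAN_30),
            _gene("c", 300, 340, CLEAN_12, isoform="short"),
            _gene("d", 390, 500, CLEAN_30),
        ]
        once = prepare_proteome(genes)
        assert prepare_proteome(once) == once


# --------------------------------------------------------------------------
# SNPs
# --------------------------------------------------------------------------


CDS_IV = [("chr1", 100, 200, "g1")]
INTRON_IV = [("chr1", 300, 400), ("chr1", 150, 180)]  # second overlaps the CDS


class TestParseSnps:
    def _tsv(self, rows):
        return io.StringIO("".join(f"{r}\n" for r in rows))

    def test_context_assignment(self):
        snps = parse_snps(
            self._tsv(["chr1\t151\tA\tG\t0.2", "chr1\t351\tC\tT\t0.1"]),
            CDS_IV,
            INTRON_IV,
        )
        assert [s.context for s in snps] == ["cds", "intron"]
        assert snps[0].gene_id == "g1"
        assert snps[0].position == 150  # 1-based file -> 0-based internal

    def test_intron_snp_overlapping_exon_dropped(self):
        snps = parse_snps(self._tsv(["chr1\t171\tA\tG\t0.2"]), [], INTRON_IV,
                          exon_intervals=CDS_IV)
        assert snps == []

    def test_identical_alleles_raise(self):
        with pytest.raises(ValueError):
            parse_snps(self._tsv(["chr1\t151\tA\tA\t0.2"]), CDS_IV, INTRON_IV)

    def test_indel_rejected(self):
        with pytest.raises(ValueError, match="indel"):
            parse_snps(self._tsv(["chr1\t151\tAT\tA\t0.2"]), CDS_IV, INTRON_IV)

    def test_multiallelic_split(self):
        snps = parse_snps(self._tsv(["chr1\t151\tA\tG,T\t0.2"]), CDS_IV, INTRON_IV)
        assert [s.alt_base for s in snps] == ["G", "T"]

    def test_vcf_parsing(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="maf">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t151\t.\tA\tG\t.\t.\tMAF=0.25\n"
        )
        snps = parse_snps(vcf, CDS_IV, INTRON_IV)
        assert len(snps) == 1
        assert snps[0].minor_allele_freq == pytest.approx(0.25)
        assert snps[0].context == "cds"

    def test_tsv_roundtrip(self, tmp_path):
        snps = parse_snps(
            self._tsv(["chr1\t151\tA\tG\t0.2", "chr1\t351\tC\tT\t0.1"]),
            CDS_IV,
            INTRON_IV,
        )
        path = tmp_path / "snps.tsv"
        phylo_io.write_snps_tsv(snps, path)
        assert phylo_io.read_snps_tsv(path) == snps


# --------------------------------------------------------------------------
# TPM and ORFs
# --------------------------------------------------------------------------


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        tpm = counts_to_tpm({"a": 5, "b": 5}, {"a": 100, "b": 100})
        assert tpm["a"] == pytest.approx(500_000)

    def test_single_gene(self):
        assert counts_to_tpm({"a": 3}, {"a": 50})["a"] == pytest.approx(1e6)

    def test_length_normalization(self):
        tpm = counts_to_tpm({"g1": 10, "g2": 10}, {"g1": 100, "g2": 200})
        assert tpm["g1"] == pytest.approx(666_666.6667, rel=1e-6)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            counts_to_tpm({"a": 1}, {"a": 0})

    @settings(max_examples=50, deadline=None)
    @given(
        st.dictionaries(
            st.text("abc", min_size=1, max_size=3),
            st.tuples(
                st.integers(min_value=0, max_value=10_000),
                st.integers(min_value=1, max_value=10_000),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_tpm_sums_to_one_million(self, data):
        counts = {g: c for g, (c, _) in data.items()}
        lengths = {g: l for g, (_, l) in data.items()}
        if sum(counts.values()) == 0:
            return
        total = sum(counts_to_tpm(counts, lengths).values())
        assert total == pytest.approx(1e6, rel=1e-6)


class TestExtractOrfs:
    def test_simple_orf(self):
        seq = "ATG" + "GCT" * 30 + "TAA"
        peps = extract_orfs(seq)
        assert peps == ["M" + "A" * 30]

    def test_no_stop_no_orf(self):
        assert extract_orfs("ATG" + "GCT" * 30) == []

    def test_ctg_start_accepted(self):
        seq = "CTG" + "GCT" * 12 + "TGA"
        assert len(extract_orfs(seq)) == 1

    def test_min_aa_filter(self):
        seq = "ATG" + "GCT" * 5 + "TAA"  # 6 aa < 10
        assert extract_orfs(seq) == []
        assert len(extract_orfs(seq, min_aa=3)) == 1

    def test_nested_orfs_keep_longest(self):
        # ATG ... ATG ... TAA in the same frame share the stop
        seq = "ATG" + "GCT" * 5 + "ATG" + "GCT" * 10 + "TAA"
        peps = extract_orfs(seq, min_aa=5)
        assert len(peps) == 1 and len(peps[0]) == 17
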