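"""Classification of gene birth events, branch dating, normalization and the
chi-square helper."""

import dataclasses

import pytest

from genebirth import gene_birth as gb
from genebirth import synthetic_data as sd
from genebirth.phylo_io import DuplicationRecord, HomologyHit, Orthogroup

MECH_TO_KLASS = {
    "de_novo": "putative_de_novo",
    "duplication": "duplicated",
    "de_novo_plus_duplicated": "de_novo_plus_duplicated",
    "conserved": "conserved",
    "contaminant": "removed_outgroup_homology",
}


class TestAssignBirthBranch:
    @pytest.mark.parametrize(
        "species, label",
        [
            ({"S_cerevisiae"}, "N0"),
            ({"S_cerevisiae", "S_paradoxus"}, "N1"),
            ({"S_cerevisiae", "S_mikatae"}, "N2"),
            ({"S_cerevisiae", "S_paradoxus", "S_mikatae"}, "N2"),
            ({"S_cerevisiae", "S_kudriavzevii"}, "N3"),
            # patchy presence: one most-distal clade species dates the branch
            ({"S_cerevisiae", "L_kluyveri"}, "N4"),
            ({"S_cerevisiae", "S_pombe"}, "N5"),
        ],
    )
    def test_most_distant_species_dates_the_birth(self, yeast_tree, species, label):
        assert gb.assign_birth_branch(species, yeast_tree) == label

    def test_reference_must_be_present(self, yeast_tree):
        with pytest.raises(ValueError):
            gb.assign_birth_branch({"S_paradoxus"}, yeast_tree)


class TestOutgroupFilter:
    def _hits(self, spec):
        return [HomologyHit("g", sp, f"{sp}|x{i}", e) for i, (sp, e) in enumerate(spec)]

    def test_two_species_below_cutoff_removes(self):
        hits = self._hits([("o1", 1e-5), ("o2", 1e-5)])
        kept, removed = gb.filter_outgroup_homology(["g"], hits)
        assert removed == ["g"] and kept == []

    def test_one_species_keeps(self):
        hits = self._hits([("o1", 1e-10), ("o1", 1e-12)])
        kept, removed = gb.filter_outgroup_homology(["g"], hits)
        assert kept == ["g"]

    def test_weak_evalues_keep(self):
        hits = self._hits([("o1", 0.01), ("o2", 0.01), ("o3", 0.01)])
        kept, removed = gb.filter_outgroup_homology(["g"], hits)
        assert kept == ["g"]


class TestMapDuplications:
    def _rec(self, node, support):
        return DuplicationRecord("OG1", node, support, ("a",), ("b",))

    def test_support_threshold(self, yeast_tree):
        recs = [self._rec("N1", 0.9), self._rec("N1", 0.2), self._rec("N2", 0.6)]
        counts = gb.map_duplications(recs, yeast_tree, support_min=0.5)
        assert counts == {"N1": 1, "N2": 1}

    def test_two_records_same_branch(self, yeast_tree):
        counts = gb.map_duplications(
            [self._rec("N0", 1.0), self._rec("N0", 0.8)], yeast_tree
        )
        assert counts == {"N0": 2}

    def test_unknown_node_raises(self, yeast_tree):
        with pytest.raises(ValueError):
            gb.map_duplications([self._rec("Nxx", 1.0)], yeast_tree)


class TestClassifyGenes:
    def _simulate(self, **kw):
        cfg = sd.SimConfig(seed=17, **kw)
        tree = cfg.tree()
        ogs, dups, hits, truth = sd.simulate_gene_histories(cfg)
        result = gb.classify_genes(ogs, dups, tree, outgroup_hits=hits)
        merged = result.frame().merge(truth.genes, on="gene_id")
        ref_rows = merged[merged.gene_id.str.startswith(tree.reference_species)]
        return tree, result, ref_rows

    def test_lossfree_recovery_is_exact(self):
        """Without lineage loss, mechanism and branch recovery are 100%."""
        tree, result, ref = self._simulate(loss_prob=0.0)
        assert len(ref) > 50
        assert (ref["class"] == ref.mechanism.map(MECH_TO_KLASS)).all()
        dated = ref[ref["class"].isin(
            ["putative_de_novo", "duplicated", "de_novo_plus_duplicated"]
        )]
        assert (dated.birth_branch == dated.branch).all()

    def test_every_reference_gene_classified_once(self):
        tree, result, ref = self._simulate(loss_prob=0.2)
        assert ref.gene_id.is_unique
        assert set(ref["class"]) <= set(gb.KLASSES)

    def test_loss_makes_genes_look_younger_never_older(self):
        """With lineage loss as the only confounder, the assigned branch
        index is always ≤ the true branch index for de novo families."""
        tree, result, ref = self._simulate(
            loss_prob=0.3, contaminant_fraction=0.0, denovo_rate=10,
            dup_rate=0, n_conserved_families=0,
        )
        dn = ref[ref.mechanism.isin(["de_novo", "de_novo_plus_duplicated"])]
        assert len(dn) > 20
        assigned = dn.birth_branch.str[1:].astype(int)
        true = dn.branch.str[1:].astype(int)
        assert (assigned <= true).all()

    def test_proteins_at_least_events(self):
        tree, result, _ = self._simulate(loss_prob=0.1)
        rates = gb.branch_rates(result, tree)
        assert (rates.n_denovo_proteins >= rates.n_denovo_events).all()
        assert (rates.n_dup_proteins >= rates.n_dup_events).all()

    def test_wgd_genes_excluded_first(self, yeast_tree):
        og = Orthogroup("OG1", {"S_cerevisiae": ("gA", "gB")})
        result = gb.classify_genes([og], [], yeast_tree, wgd_genes={"gA"})
        klass = {c.gene_id: c.klass for c in result.classifications}
        assert klass == {"gA": "excluded_wgd", "gB": "putative_de_novo"}

    def test_denovo_plus_duplicated_family_counts_both_events(self, yeast_tree):
        og = Orthogroup("OG1", {"S_cerevisiae": ("gA", "gB")})
        dup = DuplicationRecord("OG1", "N0", 1.0, ("gA",), ("gB",))
        result = gb.classify_genes([og], [dup], yeast_tree)
        assert {c.klass for c in result.classifications} == {"de_novo_plus_duplicated"}
        mechanisms = sorted(e.mechanism for e in result.events)
        assert mechanisms == ["de_novo", "duplication"]

    def test_event_gene_missing_from_orthogroup_raises(self, yeast_tree):
        og = Orthogroup("OG1", {"S_cerevisiae": ("gA",)})
        dup = DuplicationRecord("OG1", "N0", 1.0, ("gA",), ("ghost",))
        with pytest.raises(ValueError, match="ghost"):
            gb.classify_genes([og], [dup], yeast_tree)

    def test_orthogroups_without_reference_ignored(self, yeast_tree):
        og = Orthogroup("OG1", {"S_paradoxus": ("gX",)})
        result = gb.classify_genes([og], [], yeast_tree)
        assert result.classifications == []


class TestBranchRates:
    def _result_with_events(self, branch, n):
        events = [
            gb.BirthEvent(f"OG{i}", branch, "de_novo", (f"g{i}",)) for i in range(n)
        ]
        return gb.ClassificationResult([], events)

    def test_events_per_substitutions_per_100_sites(self, yeast_tree):
        """175 events on a 0.043 subs/site terminal branch → 40.70."""
        rates = gb.branch_rates(self._result_with_events("N0", 175), yeast_tree)
        row = rates.set_index("branch").loc["N0"]
        assert row.normalized_denovo == pytest.approx(175 / (100 * 0.043))
        assert row.normalized_denovo == pytest.approx(40.70, abs=0.005)

    def test_zero_events_zero_rate(self, yeast_tree):
        rates = gb.branch_rates(gb.ClassificationResult([], []), yeast_tree)
        assert (rates.normalized_denovo == 0).all()

    def test_zero_length_branch_with_events_raises(self, yeast_tree):
        # the root label has no branch above it (length 0)
        root = yeast_tree.root_label
        with pytest.raises(ValueError):
            gb.branch_rates(self._result_with_events(root, 1), yeast_tree)

    def test_normalization_linearity(self, yeast_tree):
        """Doubling every branch length halves every normalized rate."""
        from genebirth.phylo_io import parse_species_tree
        import re

        doubled = re.sub(
            r":([0-9.]+)",
            lambda m: f":{2 * float(m.group(1))}",
            yeast_tree.to_newick(),
        )
        tree2 = parse_species_tree(doubled, "S_cerevisiae")
        result = self._result_with_events("N2", 10)
        r1 = gb.branch_rates(result, yeast_tree).set_index("branch")
        r2 = gb.branch_rates(result, tree2).set_index("branch")
        assert r2.loc["N2"].normalized_denovo == pytest.approx(
            r1.loc["N2"].normalized_denovo / 2
        )


class TestYatesChisq:
    def test_worked_example(self):
        """The printed K/E 2×2 (35, 23, 1853, 2872) gives P ≈ 0.0017."""
        stat, p = gb.yates_chisq_2x2(35, 23, 1853, 2872)
        assert p == pytest.approx(0.0017, abs=0.0002)

    def test_symmetric_table(self):
        stat, p = gb.yates_chisq_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_matches_closed_form_yates_formula(self):
        """Independent oracle: χ² = N(|ad−bc|−N/2)² / ((a+b)(c+d)(a+c)(b+d))."""
        for a, b, c, d in [(35, 23, 1853, 2872), (5, 9, 14, 2), (100, 50, 60, 90)]:
            n = a + b + c + d
            num = max(abs(a * d - b * c) - n / 2, 0.0) ** 2 * n
            den = (a + b) * (c + d) * (a + c) * (b + d)
            stat, _ = gb.yates_chisq_2x2(a, b, c, d)
            assert stat == pytest.approx(num / den)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            gb.yates_chisq_2x2(0, 0, 5, 5)


class TestSyntenyFraction:
    def _setup(self):
        from genebirth.synteny_mum import MUM, SyntenyBlock

        blocks = [SyntenyBlock([MUM(0, 0, 1000)])]
        cls = [
            gb.GeneClassification("in1", "putative_de_novo", "N0"),
            gb.GeneClassification("in2", "putative_de_novo", "N0"),
            gb.GeneClassification("out1", "duplicated", "N0"),
        ]
        intervals = {
            "in1": ("chr", 100, 200),
            "in2": ("chr", 800, 900),
            "out1": ("chr", 5000, 6000),
        }
        return cls, intervals, blocks

    def test_fraction_per_class(self):
        cls, intervals, blocks = self._setup()
        frac = gb.synteny_fraction(cls, intervals, blocks)
        assert frac == {"putative_de_novo": 1.0, "duplicated": 0.0}

    def test_planted_insertion_simulation(self):
        """Genes inside conserved blocks are syntenic; genes planted in the
        insertions are not."""
        cfg = sd.SimConfig(seed=23, n_blocks=3, block_length=500,
                           insertion_length=400)
        from genebirth import synteny_mum as sm

        a, b, truth = sd.simulate_genome_pair(cfg)
        blocks = sm.cluster_mums(sm.find_mums(a, b, min_len=20), max_gap=100)
        cls, intervals = [], {}
        for i, r in enumerate(truth.blocks.itertuples(index=False)):
            gid = f"denovo{i}"
            cls.append(gb.GeneClassification(gid, "putative_de_novo", "N0"))
            intervals[gid] = ("b", r.start_b + 50, r.end_b - 50)
        for i, r in enumerate(truth.blocks.itertuples(index=False)):
            gid = f"dup{i}"
            cls.append(gb.GeneClassification(gid, "duplicated", "N0"))
            # inside the insertion immediately before the block, clear of
            # chance MUM extension at the junctions
            intervals[gid] = ("b", r.start_b - 350, r.start_b - 50)
        frac = gb.synteny_fraction(cls, intervals, blocks, genome_side="b")
        assert frac["putative_de_novo"] == 1.0
        assert frac["duplicated"] == 0.0
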