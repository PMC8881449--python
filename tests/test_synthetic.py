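"""Generator contracts: determinism, invariants, and the statistical
structure downstream stages rely on."""

from __future__ import annotations

import numpy as np
import pytest

from equimeta import io, synthetic
from equimeta.records import GenomeRecord


class TestGenomes:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = synthetic.generate_genomes(3, seed=7)
        b = synthetic.generate_genomes(3, seed=7)
        io.write_genomes(tmp_path / "a.fasta", tmp_path / "a.tsv", a)
        io.write_genomes(tmp_path / "b.fasta", tmp_path / "b.tsv", b)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_zero_plasmid_probability(self):
        genomes = synthetic.generate_genomes(4, plasmid_prob=0.0, seed=1)
        assert all(g.replicon != "plasmid" for g in genomes)

    def test_plasmids_reference_their_parent(self):
        genomes = synthetic.generate_genomes(6, plasmid_prob=1.0, seed=2)
        accs = {g.accession for g in genomes}
        plasmids = [g for g in genomes if g.replicon == "plasmid"]
        assert plasmids
        assert all(p.parent in accs for p in plasmids)

    def test_gc_fraction_matches_sequence(self):
        for g in synthetic.generate_genomes(3, seed=5):
            s = g.sequence
            assert g.gc_fraction == (s.count("G") + s.count("C")) / len(s)

    def test_each_species_has_one_to_four_members(self):
        genomes = synthetic.generate_genomes(8, seed=11)
        per_species: dict[str, int] = {}
        for g in genomes:
            if g.replicon != "plasmid":
                per_species[g.species] = per_species.get(g.species, 0) + 1
        assert len(per_species) == 8
        assert all(1 <= n <= 4 for n in per_species.values())

    def test_some_species_are_unnamed_placeholders(self):
        genomes = synthetic.generate_genomes(8, seed=11)
        assert any(not g.named for g in genomes)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_genomes(0)
        with pytest.raises(ValueError):
            synthetic.generate_genomes(2, length_range=(100, 50))


class TestSpikedGenes:
    def test_gene_is_verbatim_substring_of_host_genome(self, five_species_genomes):
        args, cazys, spiked = synthetic.spike_genes(five_species_genomes, 4, 4, seed=1)
        by_acc = {g.accession: g for g in five_species_genomes}
        arg_seqs = {a.gene_id: a.sequence for a in args}
        for sg in spiked:
            sub = by_acc[sg.accession].sequence[sg.start : sg.end]
            if sg.catalog == "ARG":
                assert arg_seqs[sg.gene_id] == sub
            else:
                from Bio.Seq import Seq

                cazy = next(c for c in cazys if c.gene_id == sg.gene_id)
                assert cazy.sequence == str(Seq(sub).translate())
                assert cazy.length_aa == (sg.end - sg.start) // 3

    def test_empty_catalogs(self, five_species_genomes):
        args, cazys, spiked = synthetic.spike_genes(five_species_genomes, 0, 0, seed=1)
        assert args == [] and cazys == [] and spiked == []

    def test_deterministic_catalogs(self, five_species_genomes):
        a = synthetic.spike_genes(five_species_genomes, 3, 3, seed=9)
        b = synthetic.spike_genes(five_species_genomes, 3, 3, seed=9)
        assert [x.sequence for x in a[0]] == [x.sequence for x in b[0]]
        assert [x.sequence for x in a[1]] == [x.sequence for x in b[1]]

    def test_replicon_restriction(self):
        genomes = synthetic.generate_genomes(5, plasmid_prob=1.0, seed=4)
        args, _, spiked = synthetic.spike_genes(
            genomes, 4, 0, seed=2, arg_replicons=("plasmid",))
        by_acc = {g.accession: g for g in genomes}
        assert all(by_acc[s.accession].replicon == "plasmid" for s in spiked)

    def test_gene_longer_than_genomes_fails(self):
        tiny = [GenomeRecord("G1", "Genus sp1", "Genus", "ACGT" * 300)]
        with pytest.raises(RuntimeError):
            synthetic.spike_genes(tiny, 1, 0, seed=0,
                                  arg_length_range=(5000, 6000))


class TestReads:
    def test_pair_bases_arithmetic(self, five_species_genomes, uniform_abundance):
        pairs, _ = synthetic.simulate_reads(
            five_species_genomes, uniform_abundance, 100, read_len=150, seed=0)
        total = sum(len(p.r1) + len(p.r2) for p in pairs)
        assert total == 100 * 2 * 150

    def test_reads_deterministic(self, five_species_genomes, uniform_abundance):
        a, _ = synthetic.simulate_reads(five_species_genomes, uniform_abundance,
                                        50, seed=3)
        b, _ = synthetic.simulate_reads(five_species_genomes, uniform_abundance,
                                        50, seed=3)
        assert [(p.r1.sequence, p.r2.sequence) for p in a] == \
            [(p.r1.sequence, p.r2.sequence) for p in b]

    def test_every_read_has_exactly_one_defect_label(
            self, five_species_genomes, uniform_abundance, host_genome):
        pairs, truths = synthetic.simulate_reads(
            five_species_genomes, uniform_abundance, 200,
            defect_rates={"ambiguous": 0.1, "low_quality": 0.1,
                          "adapter": 0.1, "host": 0.1},
            seed=1, host_genome=host_genome)
        assert len(truths) == 2 * len(pairs)
        valid = {"clean", "ambiguous", "low_quality", "adapter", "host"}
        assert all(t.defect in valid for t in truths)

    def test_defect_rate_validation(self, five_species_genomes, uniform_abundance):
        with pytest.raises(ValueError):
            synthetic.simulate_reads(five_species_genomes, uniform_abundance, 10,
                                     defect_rates={"ambiguous": 0.8,
                                                   "adapter": 0.5}, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_reads(five_species_genomes, uniform_abundance, 10,
                                     defect_rates={"bogus": 0.1}, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_reads([], {"x": 1.0}, 10, seed=0)

    def test_single_species_reads_recovered_by_profiler(self, five_species_genomes):
        from equimeta.taxprofile import ProfilerConfig, profile_cohort

        sp = five_species_genomes[0].species
        pairs, _ = synthetic.simulate_reads(five_species_genomes, {sp: 1.0},
                                            400, seed=2)
        cfg = ProfilerConfig(n_pairs_per_subsample=400, n_repeats=1,
                             rare_sample_threshold=0)
        matrix, _, _ = profile_cohort({"S1": pairs}, five_species_genomes, cfg)
        assert matrix.loc["S1", sp] >= 0.99


class TestDesign:
    def test_truth_abundances_sum_to_one(self):
        design, truth, _ = synthetic.generate_design(
            {"domestic": 3, "feral": 3}, {}, [f"sp{i}" for i in range(10)], seed=0)
        for sample in design["sample_id"]:
            assert sum(truth[sample].values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_effect_spec_has_no_signal(self):
        _, _, signal = synthetic.generate_design(
            {"domestic": 2, "feral": 2}, {}, ["a", "b"], seed=0)
        assert signal == []

    def test_fixed_seed_reproducible(self):
        a = synthetic.generate_design({"domestic": 2, "feral": 2}, {},
                                      ["a", "b", "c"], seed=5)
        b = synthetic.generate_design({"domestic": 2, "feral": 2}, {},
                                      ["a", "b", "c"], seed=5)
        assert a[0].equals(b[0]) and a[1] == b[1]

    def test_fourfold_effect_recovered_in_mean_ratio(self):
        species = [f"sp{i}" for i in range(20)]
        effect = {"sp3": {"variable": "habitat", "level": "feral", "fold": 4.0}}
        design, truth, signal = synthetic.generate_design(
            {"domestic": 20, "feral": 20}, effect, species, seed=8)
        assert signal == ["sp3"]
        feral = design.loc[design["habitat"] == "feral", "sample_id"]
        domestic = design.loc[design["habitat"] == "domestic", "sample_id"]
        ratio = (np.mean([truth[s]["sp3"] for s in feral])
                 / np.mean([truth[s]["sp3"] for s in domestic]))
        assert 2.0 <= ratio <= 8.0

    def test_nested_sites(self):
        design, _, _ = synthetic.generate_design(
            {"domestic": {"FinF": 2, "SpaS": 2}, "feral": {"Jp": 2}}, {},
            ["a", "b"], seed=0)
        assert set(design["site"]) == {"FinF", "SpaS", "Jp"}
        assert len(design) == 6
        assert design["sample_id"].is_unique

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_design({"domestic": 4}, {}, ["a"], seed=0)


class TestTaxonomy:
    def test_newick_covers_every_species(self, five_species_genomes):
        import skbio
        from io import StringIO

        nwk = synthetic.taxonomy_newick(five_species_genomes)
        tree = skbio.TreeNode.read(StringIO(nwk))
        tips = {t.name for t in tree.tips()}
        assert tips == {g.species for g in five_species_genomes}
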