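"""Simulator contracts: tree/taxonomy structure, transfer process, sequence
evolution, determinism, fixture files."""

import math

import numpy as np
import pytest
from scipy import stats

from hgtscreen.core import parse_newick, read_fasta, read_gene_table, read_taxonomy, write_newick
from hgtscreen.simulate import (
    SimConfig,
    evolve_sequences,
    read_truth_table,
    simulate_dataset,
    simulate_gene_families,
    simulate_species_tree,
    write_fixture,
)
from hgtscreen.trees import bipartition_set


class TestSpeciesTree:
    def test_contract_small_two_phyla(self):
        cfg = SimConfig(n_taxa=8, n_phyla=2, seed=1, focal_clade_size=1)
        tree, tax = simulate_species_tree(cfg)
        assert len(tax) == 8
        assert len({l.phylum for l in tax.values()}) == 2
        focal = [l for l in tax.values() if l.is_focal]
        assert len(focal) == 1
        # with a focal clade of one, the focal organism is alone in its phylum
        assert sum(1 for l in tax.values() if l.phylum == focal[0].phylum) == 1

    def test_focal_clade_is_monophyletic_phylum(self):
        cfg = SimConfig(n_taxa=20, n_phyla=4, seed=3)
        tree, tax = simulate_species_tree(cfg)
        focal = next(l for l in tax.values() if l.is_focal)
        clade = {g for g, l in tax.items() if l.phylum == focal.phylum}
        assert len(clade) == cfg.focal_clade_size
        mrca = tree.tree.mrca(taxon_labels=sorted(clade))
        assert {lf.taxon.label for lf in mrca.leaf_iter()} == clade

    def test_phyla_are_monophyletic(self):
        cfg = SimConfig(n_taxa=24, n_phyla=5, seed=7)
        tree, tax = simulate_species_tree(cfg)
        phyla = {}
        for g, l in tax.items():
            phyla.setdefault(l.phylum, set()).add(g)
        assert len(phyla) == 5
        for members in phyla.values():
            mrca = tree.tree.mrca(taxon_labels=sorted(members))
            assert {lf.taxon.label for lf in mrca.leaf_iter()} == members

    def test_ultrametric_within_tolerance(self):
        cfg = SimConfig(n_taxa=16, n_phyla=3, seed=5, tree_depth=0.5)
        tree, _ = simulate_species_tree(cfg)
        tree.tree.calc_node_root_distances()
        depths = [lf.root_distance for lf in tree.tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(0.5)
        assert max(depths) - min(depths) < 1e-9

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_taxa=10, n_phyla=2, seed=9)
        t1, _ = simulate_species_tree(cfg)
        t2, _ = simulate_species_tree(cfg)
        assert write_newick(t1) == write_newick(t2)

    def test_unattainable_phyla_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            SimConfig(n_taxa=8, n_phyla=8, focal_clade_size=3).validate()


class TestGeneFamilies:
    def test_no_transfers_means_species_topology(self):
        cfg = SimConfig(n_taxa=10, n_phyla=2, n_families=6, p_transfer=0.0, seed=2)
        tree, tax = simulate_species_tree(cfg)
        fams, events = simulate_gene_families(tree, tax, cfg)
        assert events == []
        want = {frozenset(l.split("_")[0] for l in s) for s in bipartition_set(tree)}
        for fam, gt in fams:
            got = {frozenset(l.split("_")[0] for l in s) for s in bipartition_set(gt)}
            assert got == want

    def test_certain_transfer_every_family(self):
        cfg = SimConfig(n_taxa=10, n_phyla=2, n_families=10, p_transfer=1.0, seed=2)
        tree, tax = simulate_species_tree(cfg)
        _, events = simulate_gene_families(tree, tax, cfg)
        assert len(events) == 10
        focal_phylum = next(l.phylum for l in tax.values() if l.is_focal)
        assert all(e.donor_phylum != focal_phylum for e in events)

    def test_event_count_within_binomial_band(self):
        cfg = SimConfig(n_taxa=10, n_phyla=2, n_families=1000, p_transfer=0.3, seed=4, seq_length=50)
        tree, tax = simulate_species_tree(cfg)
        _, events = simulate_gene_families(tree, tax, cfg)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1000, 0.3)
        assert lo <= len(events) <= hi

    def test_transfer_moves_never_deletes_focal(self):
        cfg = SimConfig(n_taxa=12, n_phyla=3, n_families=8, p_transfer=0.7, seed=6)
        tree, tax = simulate_species_tree(cfg)
        fams, _ = simulate_gene_families(tree, tax, cfg)
        species_genomes = set(tax)
        for fam, gt in fams:
            assert {l.rsplit("_", 1)[0] for l in gt.leaf_labels()} == species_genomes

    def test_transferred_tip_sister_to_donor(self):
        cfg = SimConfig(n_taxa=12, n_phyla=3, n_families=12, p_transfer=1.0, seed=8)
        tree, tax = simulate_species_tree(cfg)
        fams, events = simulate_gene_families(tree, tax, cfg)
        focal = next(l.genome_id for l in tax.values() if l.is_focal)
        by_fam = {e.family_id: e for e in events}
        for fam, gt in fams:
            focal_leaf = next(l for l in gt.leaf_labels() if l.startswith(f"{focal}_"))
            node = next(lf for lf in gt.tree.leaf_node_iter() if lf.taxon.label == focal_leaf)
            siblings = {
                lf.taxon.label.rsplit("_", 1)[0]
                for ch in node.parent_node.child_nodes()
                if ch is not node
                for lf in ch.leaf_iter()
            }
            assert siblings == {by_fam[fam].donor_genome}


class TestEvolveSequences:
    def test_zero_distance_identical(self):
        cfg = SimConfig(n_taxa=8, n_phyla=2, seq_length=100, seed=1)
        gt = parse_newick("(A:0,B:0);", rooted=True)
        seqs = dict(evolve_sequences(gt, cfg))
        assert seqs["A"] == seqs["B"] and len(seqs["A"]) == 100

    def test_jc_saturation_limit(self):
        """At branch length 10 the expected fraction of differing sites is
        essentially the JC limit 3/4."""
        cfg = SimConfig(n_taxa=8, n_phyla=2, seq_length=10000, seed=2)
        gt = parse_newick("(A:5,B:5);", rooted=True)
        seqs = dict(evolve_sequences(gt, cfg))
        diff = np.mean([x != y for x, y in zip(seqs["A"], seqs["B"])])
        se = math.sqrt(0.75 * 0.25 / 10000)
        assert abs(diff - 0.75) < 5 * se

    def test_k2p_transition_bias(self):
        cfg = SimConfig(n_taxa=8, n_phyla=2, seq_length=20000, seed=3, subst_model="K2P", kappa=8.0)
        gt = parse_newick("(A:0.0001,B:0.3);", rooted=True)
        seqs = dict(evolve_sequences(gt, cfg))
        ts = tv = 0
        purines = {"A", "G"}
        for x, y in zip(seqs["A"], seqs["B"]):
            if x == y:
                continue
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
        assert ts > tv  # strong kappa means transitions dominate

    def test_same_seed_identical_output(self):
        cfg = SimConfig(n_taxa=8, n_phyla=2, seq_length=80, seed=4)
        gt = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);", rooted=True)
        assert evolve_sequences(gt, cfg) == evolve_sequences(gt, cfg)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="seq_length"):
            SimConfig(n_taxa=8, n_phyla=2, seq_length=10).validate()


class TestWriteFixture:
    def test_files_and_counts(self, small_sim, small_fixture_dir):
        paths = small_fixture_dir
        fam_fastas = sorted(paths["families_dir"].glob("*.fasta"))
        assert len(fam_fastas) == len(small_sim.families)
        truth = read_truth_table(paths["truth"])
        assert len(truth) == len(small_sim.truth_events)
        tax = read_taxonomy(paths["taxonomy"])
        assert set(tax) == set(small_sim.taxonomy)
        genes = read_gene_table(paths["gene_table"])
        assert len(genes) == len(small_sim.gene_table)
        seqs = read_fasta(paths["fasta"])
        assert len(seqs) == len(genes)

    def test_rerun_byte_identical(self, small_sim, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(d1, small_sim)
        write_fixture(d2, small_sim)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_gene_layout_spacing(self, small_sim):
        genes = [g for g in small_sim.gene_table if g.genome_id == small_sim.focal_genome]
        genes.sort(key=lambda g: g.start)
        gaps = {b.start - a.end - 1 for a, b in zip(genes, genes[1:])}
        assert gaps == {100}
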