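"""Planted-structure guarantees of the synthetic community generator."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from pbinkit.pbin import ModulePartition, barber_modularity, nodf
from pbinkit.synthetic_data import SynthConfig, Synthesizer


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(edge_noise=1.5)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_samples=0)

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(nestedness_shape=0)


class TestGeneratePbin:
    def test_theta_one_square_module_is_strict_triangle(self):
        cfg = SynthConfig(n_modules=1, bacteria_per_module=4, phages_per_module=4, seed=0)
        net, _ = Synthesizer(cfg).generate_pbin()
        assert nodf(net.matrix) == pytest.approx(100.0)
        assert list(net.matrix.sum(axis=0)) == [4, 3, 2, 1]

    def test_noise_free_matrix_is_block_diagonal(self):
        cfg = SynthConfig(seed=1)
        net, truth = Synthesizer(cfg).generate_pbin()
        df = net.to_dataframe()
        for b in df.index:
            for v in df.columns:
                if truth.botu_modules[b] != truth.votu_modules[v]:
                    assert df.loc[b, v] == 0

    def test_no_empty_rows_or_columns_without_noise(self):
        cfg = SynthConfig(nestedness_shape=2.5, seed=2)
        net, _ = Synthesizer(cfg).generate_pbin()
        assert (net.row_degrees > 0).all()
        assert (net.col_degrees > 0).all()

    def test_full_cross_module_rate_beats_planted_partition(self):
        # delta=1 connects everything: the planted partition scores below the
        # trivial single-module baseline (Q = 0) under Barber's formula
        cfg = SynthConfig(cross_module_rate=1.0, edge_noise=0.0, seed=3)
        net, truth = Synthesizer(cfg).generate_pbin()
        df = net.to_dataframe()
        for b in df.index:  # every cross-module cell switched on
            for v in df.columns:
                if truth.botu_modules[b] != truth.votu_modules[v]:
                    assert df.loc[b, v] == 1
        planted = ModulePartition(truth.botu_modules, truth.votu_modules, q=0.0)
        assert barber_modularity(net, planted) < 0.0

    def test_broad_phages_have_broader_susceptibility(self):
        cfg = SynthConfig(seed=4)
        _, truth = Synthesizer(cfg).generate_pbin()
        # rank-1 phage of module 1 reaches more (host, strain) pairs than rank-8
        broad = sum(
            len(s) for (b, v), s in truth.susceptibility.items() if v == "vOTU_m1_01"
        )
        narrow = sum(
            len(s) for (b, v), s in truth.susceptibility.items() if v == "vOTU_m1_08"
        )
        assert broad > narrow

    def test_expected_nodf_nonincreasing_in_edge_noise(self):
        means = []
        for eps in (0.0, 0.1, 0.3):
            vals = []
            for seed in range(50):
                cfg = SynthConfig(
                    n_modules=1, bacteria_per_module=6, phages_per_module=8,
                    edge_noise=eps, seed=seed,
                )
                net, _ = Synthesizer(cfg).generate_pbin()
                if net.n_edges:
                    vals.append(nodf(net.matrix))
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestGenerateTree:
    def test_two_modules_of_two_are_cherries(self):
        cfg = SynthConfig(n_modules=2, bacteria_per_module=2, phages_per_module=2, seed=5)
        syn = Synthesizer(cfg)
        syn.generate_pbin()
        newick = syn.generate_tree()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 4
        for leaf in tree.leaf_nodes():
            sibs = {l.taxon.label.replace(" ", "_") for l in leaf.parent_node.leaf_iter()}
            assert len(sibs) == 2
            assert len({s.split("_m")[1].split("_")[0] for s in sibs}) == 1

    def test_modules_are_monophyletic(self):
        cfg = SynthConfig(seed=6)
        syn = Synthesizer(cfg)
        _, truth = syn.generate_pbin()
        tree = dendropy.Tree.get(data=syn.generate_tree(), schema="newick")
        tree.is_rooted = True
        taxon_ns = tree.taxon_namespace
        for m in range(1, cfg.n_modules + 1):
            tips = [b.replace("_", " ") for b in truth.botus if truth.botu_modules[b] == m]
            mrca = tree.mrca(taxa=[taxon_ns.get_taxon(t) for t in tips])
            assert len(mrca.leaf_nodes()) == len(tips)

    def test_same_seed_identical_newick(self):
        def build():
            syn = Synthesizer(SynthConfig(seed=7))
            syn.generate_pbin()
            return syn.generate_tree()

        assert build() == build()


class TestGenerateCommunity:
    def test_single_strain_genomes_are_monomorphic(self):
        cfg = SynthConfig(
            n_modules=1, bacteria_per_module=2, phages_per_module=2,
            strains_per_botu=1, strain_occupancy=1.0, n_samples=3,
            genome_length=300, mean_coverage=80, seed=8,
        )
        syn = Synthesizer(cfg)
        art = syn.run()
        truth = art["truth"]
        assert all(v == 0.0 for v in truth.true_pi.values() if not np.isnan(v))
        from pbinkit.profiles import genome_pi

        for _, table in art["alleles"].groupby(["sample_id", "botu_id"]):
            assert genome_pi(table) == 0.0  # no sampling noise: one haplotype

    def test_two_strain_true_pi_matches_closed_form(self):
        cfg = SynthConfig(
            n_modules=1, bacteria_per_module=1, phages_per_module=2,
            strains_per_botu=2, strain_occupancy=1.0, n_samples=2,
            genome_length=1000, snv_rate=0.02, seed=9,
        )
        syn = Synthesizer(cfg)
        art = syn.run()
        truth = art["truth"]
        botu = truth.botus[0]
        alleles = truth.strain_alleles[botu]
        n_var = int((alleles[0] != alleles[1]).sum())
        assert n_var == 20  # snv_rate * L, both strains differ at every variant
        for s in ("bee_001", "bee_002"):
            present, w = truth.occupancy[(s, botu)]
            if len(present) < 2:
                continue
            expect = n_var / cfg.genome_length * 2 * w[0] * (1 - w[0])
            assert truth.true_pi[(s, botu)] == pytest.approx(expect)

    def test_votu_presence_requires_susceptible_host_strain(self):
        cfg = SynthConfig(phage_dropout=0.0, seed=10, genome_length=200)
        syn = Synthesizer(cfg)
        art = syn.run()
        truth = art["truth"]
        pres = truth.votu_presence
        for s in pres.index:
            for v in pres.columns:
                hosts = [k for k in truth.susceptibility if k[1] == v]
                has_host = any(
                    bool(set(truth.occupancy[(s, b)][0] + 1) & truth.susceptibility[(b, v)])
                    for b, _ in hosts
                )
                assert bool(pres.loc[s, v]) == has_host

    def test_coverage_summaries_respect_presence_thresholds(self, small_artifacts):
        from pbinkit.profiles import call_presence

        cov = small_artifacts["coverage"]
        truth = small_artifacts["truth"]
        pres_v = call_presence(cov[cov["kind"] == "votu"], "votu")
        pd.testing.assert_frame_equal(
            pres_v.sort_index(axis=1), truth.votu_presence.sort_index(axis=1),
            check_dtype=False, check_names=False,
        )
        pres_b = call_presence(cov[cov["kind"] == "botu"], "botu")
        for (s, b), (present, _) in truth.occupancy.items():
            assert bool(pres_b.loc[s, b]) == (len(present) > 0)


class TestGenerateEvidence:
    def test_conservation_every_edge_has_evidence(self, small_artifacts):
        truth = small_artifacts["truth"]
        ledger = truth.evidence_ledger
        real = ledger[~ledger["is_decoy"]]
        assert set(zip(real["botu_id"], real["votu_id"])) == truth.true_edges

    def test_planted_mismatch_budget_respected(self, small_artifacts):
        from pbinkit.linkage import match_spacers

        art = small_artifacts
        matches = match_spacers(art["spacers"], art["viral_seqs"])
        by_spacer = {}
        for m in matches:
            by_spacer.setdefault(m.spacer_id, []).append(m)
        ledger = art["truth"].evidence_ledger
        for row in ledger[ledger["kind"] == "crispr"].itertuples(index=False):
            best = min(
                (m.mismatches for m in by_spacer.get(row.record_id, [])
                 if m.target_contig_id == row.votu_id),
                default=None,
            )
            assert best is not None and best <= row.mismatches

    def test_three_mismatch_decoys_not_recovered(self):
        from pbinkit.linkage import match_spacers

        cfg = SynthConfig(n_decoy_spacers=10, seed=12)
        art = Synthesizer(cfg).run()
        ledger = art["truth"].evidence_ledger
        decoy_ids = set(ledger.loc[ledger["is_decoy"] & (ledger["kind"] == "crispr"), "record_id"])
        matches = match_spacers(art["spacers"], art["viral_seqs"])
        decoy_hits = {}
        for m in matches:
            if m.spacer_id in decoy_ids:
                decoy_hits.setdefault(m.spacer_id, []).append(m)
        # a decoy must not match its own planted target (3 mismatches > 2)
        for row in ledger[ledger["is_decoy"] & (ledger["kind"] == "crispr")].itertuples(index=False):
            assert not any(
                m.target_contig_id == row.votu_id for m in decoy_hits.get(row.record_id, [])
            )

    def test_decoy_homology_below_thresholds(self):
        from pbinkit.linkage import link_by_homology

        cfg = SynthConfig(n_decoy_homology=10, seed=13)
        art = Synthesizer(cfg).run()
        links = link_by_homology(art["homology"])
        linked = set(zip(links["vmag_id"], links["genome_id"]))
        ledger = art["truth"].evidence_ledger
        for row in ledger[ledger["is_decoy"] & (ledger["kind"] == "homology")].itertuples(index=False):
            votu, genome = row.record_id.split("|")
            assert (votu, genome) not in linked

    def test_zero_evidence_probs_give_no_records(self):
        cfg = SynthConfig(evidence_crispr_prob=0.0, evidence_homology_prob=0.0, seed=14)
        art = Synthesizer(cfg).run()
        assert art["spacers"] == []
        assert art["homology"].empty


class TestProteomeEdges:
    def test_edges_enriched_within_modules(self):
        syn = Synthesizer(SynthConfig(seed=15))
        _, truth = syn.generate_pbin()
        edges = syn.generate_proteome_edges()
        same = sum(
            truth.votu_modules[a] == truth.votu_modules[b]
            for a, b in zip(edges["node_a"], edges["node_b"])
        )
        assert same / len(edges) > 0.8

    def test_neighborhood_purity_high_on_planted_modules(self):
        from pbinkit.pbin import neighborhood_purity

        syn = Synthesizer(SynthConfig(seed=16))
        _, truth = syn.generate_pbin()
        edges = syn.generate_proteome_edges()
        out = neighborhood_purity(
            list(zip(edges["node_a"], edges["node_b"])), truth.votu_modules
        )
        purities = [p.purity for p in out if p.purity == p.purity]
        assert np.mean(purities) > 0.8


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = dict(n_samples=4, genome_length=200, seed=21)
        p1 = Synthesizer(SynthConfig(**cfg)).write_inputs(tmp_path / "a")
        p2 = Synthesizer(SynthConfig(**cfg)).write_inputs(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_changes_outputs(self, tmp_path):
        a = Synthesizer(SynthConfig(n_samples=3, genome_length=200, seed=1)).run()
        b = Synthesizer(SynthConfig(n_samples=3, genome_length=200, seed=2)).run()
        assert not a["alleles"].equals(b["alleles"])
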