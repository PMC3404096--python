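"""Synthetic pangenome generator: truth structure, event log, emitted tables."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from halotribes import (
    SimParams,
    emit_annotations,
    emit_profile_hits,
    emit_similarity_hits,
    generate_pangenome,
)
from halotribes.simulate import write_outputs


def _params(**kw):
    base = dict(
        n_core_tribes=50,
        n_genus_tribes={"Haloferax": 10, "Haloarcula": 10},
        seed=1,
    )
    base.update(kw)
    return SimParams(**base)


class TestGeneratePangenome:
    def test_no_flux_limit_all_core_tribes_everywhere(self):
        p = _params(loss_rate=0.0, gain_rate=0.0, n_core_tribes=100)
        truth = generate_pangenome(p)
        core = truth.presence.loc[truth.presence.index.str.startswith("CORE")]
        assert core.shape[0] == 100
        assert (core.to_numpy() == 1).all()

    def test_genus_tribes_confined_without_gain(self):
        p = _params(loss_rate=0.0, gain_rate=0.0)
        truth = generate_pangenome(p)
        fx = truth.presence.loc[truth.presence.index.str.startswith("HALOFERAX")]
        assert (fx[[c for c in fx.columns if c.startswith("Haloferax")]] == 1).all().all()
        assert (fx[[c for c in fx.columns if c.startswith("Haloarcula")]] == 0).all().all()

    def test_same_seed_identical_event_logs(self):
        p = _params(seed=42)
        a, b = generate_pangenome(p), generate_pangenome(p)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.presence, b.presence)

    def test_different_seed_differs(self):
        a = generate_pangenome(_params(seed=1))
        b = generate_pangenome(_params(seed=2))
        assert not a.presence.equals(b.presence)

    def test_every_gene_in_exactly_one_tribe(self, small_truth):
        seen = {}
        for tribe in small_truth.tribes:
            for g in tribe.members:
                assert g not in seen
                seen[g] = tribe.tribe_id
        assert set(seen) == set(small_truth.genes["gene_id"])

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ValueError, match="loss_rate"):
            _params(loss_rate=1.5)
        with pytest.raises(ValueError, match="clade_loss_boost"):
            _params(clade_loss_boost=0.5)
        with pytest.raises(ValueError, match="n_genomes_per_genus"):
            SimParams(n_genomes_per_genus={"A": 0, "B": 4})
        with pytest.raises(ValueError, match="cog_effect"):
            _params(cog_effect={"!": {"Haloferax": 0.1}})

    def test_event_log_conservation(self, small_truth):
        """Leaf presence equals root presence XOR parity of path toggles."""
        tree = dendropy.Tree.get(
            data=small_truth.tree_newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        toggles = small_truth.events.groupby(["node", "tribe_id"]).size()
        root_present = {
            t: t.startswith("CORE") for t in small_truth.presence.index
        }
        for leaf in tree.leaf_node_iter():
            path = []
            node = leaf
            while node.parent_node is not None:
                label = node.taxon.label if node.taxon else node.label
                path.append(label)
                node = node.parent_node
            genome = leaf.taxon.label
            for tribe in small_truth.presence.index:
                parity = sum(toggles.get((n, tribe), 0) for n in path) % 2
                expected = root_present[tribe] ^ bool(parity)
                assert bool(small_truth.presence.loc[tribe, genome]) == expected

    def test_clade_loss_boost_scales_per_branch_losses(self):
        """Monte-Carlo mean losses per boosted branch are ~10x background.

        With loss_rate small and gains off, attrition is negligible and
        the closed-form expectation per branch is rate * n_tribes.
        """
        n_core, rate, boost = 500, 0.002, 10.0
        boosted_nodes = background_nodes = None
        boosted_losses, background_losses = [], []
        n_seeds = 200
        for seed in range(n_seeds):
            p = SimParams(
                n_core_tribes=n_core,
                n_genus_tribes={"Haloferax": 0, "Haloarcula": 0},
                loss_rate=rate,
                gain_rate=0.0,
                clade_loss_boost=boost,
                seed=seed,
            )
            truth = generate_pangenome(p)
            if boosted_nodes is None:
                tree = dendropy.Tree.get(
                    data=truth.tree_newick, schema="newick",
                    preserve_underscores=True, suppress_internal_node_taxa=False,
                )
                boost_set = {"Haloferax_g3", "Haloferax_g4", "Haloferax_g5"}
                boosted_nodes, background_nodes = set(), set()
                for node in tree.preorder_node_iter():
                    if node.parent_node is None:
                        continue
                    label = node.taxon.label if node.taxon else node.label
                    leaves = {lf.taxon.label for lf in node.leaf_iter()}
                    (boosted_nodes if leaves <= boost_set else background_nodes).add(label)
            losses = truth.events.loc[truth.events["event"] == "loss", "node"]
            counts = losses.value_counts()
            boosted_losses.append(
                sum(counts.get(n, 0) for n in boosted_nodes) / len(boosted_nodes)
            )
            background_losses.append(
                sum(counts.get(n, 0) for n in background_nodes) / len(background_nodes)
            )
        mean_boosted = np.mean(boosted_losses)
        mean_background = np.mean(background_losses)
        expected = boost * rate * n_core
        assert mean_boosted == pytest.approx(expected, rel=0.10)
        assert mean_boosted / mean_background == pytest.approx(boost, rel=0.15)


class TestEmitSimilarityHits:
    def test_within_tribe_scores_exceed_decoys_without_noise(self):
        p = _params(score_noise_sd=0.0, decoy_fraction=0.2)
        truth = generate_pangenome(p)
        hits = emit_similarity_hits(truth, p)
        tribe_of = dict(zip(truth.genes["gene_id"], truth.genes["tribe_id"]))
        within = hits["query_id"].map(tribe_of) == hits["subject_id"].map(tribe_of)
        assert within.any() and (~within).any()
        assert hits.loc[within, "bitscore"].min() > hits.loc[~within, "bitscore"].max()

    def test_single_tribe_emits_all_directed_pairs(self):
        p = _params(
            n_core_tribes=1,
            n_genus_tribes={"Haloferax": 0, "Haloarcula": 0},
            loss_rate=0.0, gain_rate=0.0, decoy_fraction=0.0,
        )
        truth = generate_pangenome(p)
        k = len(truth.genes)
        hits = emit_similarity_hits(truth, p)
        assert len(hits) == k * (k - 1)
        assert not (hits["query_id"] == hits["subject_id"]).any()

    def test_empty_truth_empty_table(self):
        p = _params(n_core_tribes=0, n_genus_tribes={"Haloferax": 0, "Haloarcula": 0})
        truth = generate_pangenome(p)
        assert emit_similarity_hits(truth, p).empty

    def test_coverages_and_evalues_valid(self, small_truth, small_params):
        hits = emit_similarity_hits(small_truth, small_params)
        assert hits["q_cov"].between(0, 1).all()
        assert hits["s_cov"].between(0, 1).all()
        assert (hits["evalue"] >= 0).all()
        # E-value is a monotone transform of bit score
        h = hits.sort_values("bitscore")
        assert (np.diff(h["evalue"].to_numpy()) <= 1e-30).all()


class TestEmitProfileHits:
    def test_true_hits_inside_filters(self, small_truth, small_params):
        ph = emit_profile_hits(small_truth, small_params)
        tribe_of = dict(zip(small_truth.genes["gene_id"], small_truth.genes["tribe_id"]))
        is_true = ph["gene_id"].map(tribe_of) == ph["profile_id"]
        assert (ph.loc[is_true, "evalue"] < 1e-6).all()
        assert (ph.loc[is_true, ["cov_gene", "cov_profile"]] > 0.9).all().all()

    def test_decoys_straddle_thresholds(self, small_truth, small_params):
        ph = emit_profile_hits(small_truth, small_params)
        tribe_of = dict(zip(small_truth.genes["gene_id"], small_truth.genes["tribe_id"]))
        decoys = ph.loc[ph["gene_id"].map(tribe_of) != ph["profile_id"]]
        assert (decoys["evalue"] < 1e-4).any() and (decoys["evalue"] >= 1e-4).any()
        assert (decoys["cov_gene"] > 0.8).any() and (decoys["cov_gene"] <= 0.8).any()

    def test_best_hit_assignment_unique_per_gene(self, small_truth, small_params):
        from halotribes import assign_best_profile, filter_profile_hits

        ph = emit_profile_hits(small_truth, small_params)
        assignments = assign_best_profile(filter_profile_hits(ph))
        # mapping: each gene appears exactly once by construction
        assert len(assignments) == len(set(assignments))
        # brute force: the assigned profile minimises the E-value
        filtered = filter_profile_hits(ph)
        for gene, profile in list(assignments.items())[:50]:
            sub = filtered.loc[filtered["gene_id"] == gene]
            assert sub.loc[sub["profile_id"] == profile, "evalue"].min() == sub["evalue"].min()


class TestEmitAnnotations:
    def test_cog_fraction_targets_met_in_expectation(self):
        """Mean realized fractions over 100 seeds are within 0.002 of the
        per-genus targets 0.042 / 0.030."""
        sums = {"Haloferax": [], "Haloarcula": []}
        for seed in range(100):
            p = SimParams(
                n_core_tribes=600,
                n_genus_tribes={"Haloferax": 150, "Haloarcula": 150},
                cog_effect={"T": {"Haloferax": 0.030, "Haloarcula": 0.042}},
                seed=seed,
            )
            truth = generate_pangenome(p)
            ann = emit_annotations(truth, p)
            has_t = ann["cog"].str.contains("T", regex=False)
            frac = has_t.groupby(ann["genome_id"]).mean()
            for genus in sums:
                cols = [g for g in frac.index if g.startswith(genus)]
                sums[genus].append(frac[cols].mean())
        assert np.mean(sums["Haloferax"]) == pytest.approx(0.030, abs=0.002)
        assert np.mean(sums["Haloarcula"]) == pytest.approx(0.042, abs=0.002)

    def test_zero_rate_category_has_zero_fraction(self):
        p = _params(cog_effect={"T": {"Haloferax": 0.0, "Haloarcula": 0.05}})
        truth = generate_pangenome(p)
        ann = emit_annotations(truth, p)
        fx = ann.loc[ann["genus_id"] == "Haloferax"]
        assert not fx["cog"].str.contains("T", regex=False).any()

    def test_known_product_counts_are_recoverable(self):
        from halotribes import screen_by_annotation

        p = _params(product_fidelity=1.0)
        truth = generate_pangenome(p)
        ann = emit_annotations(truth, p)
        counts = screen_by_annotation(ann, ["cellulase"])
        manual = (
            ann["product"].str.lower().str.contains("cellulase")
            .groupby(ann["genome_id"]).sum()
        )
        for g in counts.index:
            assert counts.loc[g, "cellulase"] == manual.get(g, 0)


class TestDeterminism:
    def test_written_outputs_byte_identical(self, tmp_path):
        p = _params(seed=9)
        for sub in ("a", "b"):
            truth = generate_pangenome(p)
            write_outputs(truth, p, tmp_path / sub)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_user_newick_topology_respected(self):
        nwk = (
            "((Haloferax_g1,(Haloferax_g2,Haloferax_g3)),"
            "(Haloarcula_g1,Haloarcula_g2));"
        )
        p = SimParams(
            n_genomes_per_genus={"Haloferax": 3, "Haloarcula": 2},
            n_core_tribes=20,
            n_genus_tribes={"Haloferax": 5, "Haloarcula": 5},
            tree_newick=nwk,
            seed=0,
        )
        truth = generate_pangenome(p)
        assert set(truth.presence.columns) == {
            "Haloferax_g1", "Haloferax_g2", "Haloferax_g3",
            "Haloarcula_g1", "Haloarcula_g2",
        }
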