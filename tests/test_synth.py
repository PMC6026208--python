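import numpy as np
import pytest

from flyscreen import synth


class TestLattice:
    def test_noise_free_lattice_has_all_sites_on_offset_grid(self):
        spec = synth.LatticeSpec(jitter_sigma=0, dropout_rate=0,
                                 fusion_rate=0, background_noise_sd=0, seed=0)
        _, centers = synth.generate_eye_image(spec)
        assert len(centers) == 400
        ideal = synth.ideal_lattice(spec)
        assert np.allclose(np.sort(centers, axis=0), np.sort(ideal, axis=0))
        # odd rows shifted by half a spacing, rows spacing*sqrt(3)/2 apart
        ys = np.unique(np.round(ideal[:, 1], 6))
        assert np.allclose(np.diff(ys), spec.spacing * np.sqrt(3) / 2)

    def test_same_seed_gives_identical_image_bytes(self):
        spec = synth.LatticeSpec(dropout_rate=0.05, seed=11)
        img1, t1 = synth.generate_eye_image(spec)
        img2, t2 = synth.generate_eye_image(spec)
        assert img1.pixels.tobytes() == img2.pixels.tobytes()
        assert np.array_equal(t1, t2)
        img3, _ = synth.generate_eye_image(
            synth.LatticeSpec(dropout_rate=0.05, seed=12))
        assert img1.pixels.tobytes() != img3.pixels.tobytes()

    def test_dropout_removes_a_binomial_number_of_sites(self):
        spec = synth.LatticeSpec(dropout_rate=0.05, seed=21)
        _, centers = synth.generate_eye_image(spec)
        assert 400 * 0.85 < len(centers) < 400  # well within binomial range

    def test_jitter_offsets_have_the_requested_spread(self):
        # same seed, sigma=0 vs sigma=3: the standard-normal draws are
        # shared, so the difference is exactly the injected offsets
        base = synth.LatticeSpec(jitter_sigma=0, background_noise_sd=0, seed=5)
        jit = synth.LatticeSpec(jitter_sigma=3, background_noise_sd=0, seed=5)
        _, c0 = synth.generate_eye_image(base)
        _, c3 = synth.generate_eye_image(jit)
        offsets = c3 - c0
        for axis in (0, 1):
            assert abs(np.std(offsets[:, axis]) - 3.0) < 0.3

    def test_fusion_replaces_two_sites_with_their_midpoint(self):
        spec = synth.LatticeSpec(n_rows=6, n_cols=6, fusion_rate=0.5,
                                 background_noise_sd=0, seed=3)
        _, centers = synth.generate_eye_image(spec)
        assert len(centers) < 36
        ideal = synth.ideal_lattice(spec)
        # every non-ideal center must be a midpoint of two ideal sites
        from scipy.spatial import cKDTree
        tree = cKDTree(ideal)
        d, _ = tree.query(centers)
        fused = centers[d > 1e-9]
        assert len(fused) > 0
        for point in fused:
            dd, _ = tree.query(point, k=2)
            assert np.allclose(dd[0], dd[1], atol=1e-9)

    def test_intensities_stay_in_declared_range(self):
        img, _ = synth.generate_eye_image(
            synth.LatticeSpec(background_noise_sd=0.3, seed=4))
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    @pytest.mark.parametrize("kwargs", [
        {"n_rows": 0}, {"spacing": 2.0, "ommatidium_radius": 3.0},
        {"dropout_rate": 1.5}, {"jitter_sigma": -1},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.LatticeSpec(**kwargs)


class TestScoreTables:
    def test_no_interaction_pair_leaves_b_cells_at_background(self):
        truth = synth.InteractionTruth("a", "b", "none", effect_a=10,
                                       effect_b=0, interaction_shift=0,
                                       within_sd=0.5, n_replicates=200)
        table = synth.generate_score_table([truth], 20.0, seed=0)
        means = table.groupby("genotype")["score"].mean()
        assert abs(means["B"] - means["control"]) < 0.2
        assert abs(means["AB"] - means["A"]) < 0.2

    def test_additive_pair_two_hit_mean_is_sum_of_effects(self):
        truth = synth.InteractionTruth("a", "b", "additive", effect_a=10,
                                       effect_b=5, within_sd=0.5,
                                       n_replicates=500)
        table = synth.generate_score_table([truth], 20.0, seed=1)
        ab = table.loc[table.genotype == "AB", "score"].mean()
        assert abs(ab - 35.0) < 0.2

    def test_suppressor_contrast_concentrates_near_planted_shift(self):
        truth = synth.InteractionTruth("a", "b", "suppressor", effect_a=10,
                                       effect_b=5, interaction_shift=-8,
                                       within_sd=1, n_replicates=12)
        table = synth.generate_score_table([truth], 20.0, seed=2)
        m = table.groupby("genotype")["score"].mean()
        contrast = (m["AB"] - m["A"]) - (m["B"] - m["control"])
        assert abs(contrast - (-8)) < 1.0

    def test_full_rescue_two_hit_mean_equals_control(self):
        truth = synth.InteractionTruth("a", "b", "full_rescue", effect_a=10,
                                       within_sd=0.5, n_replicates=300)
        table = synth.generate_score_table([truth], 20.0, seed=3)
        m = table.groupby("genotype")["score"].mean()
        assert abs(m["AB"] - m["control"]) < 0.2

    def test_class_shift_consistency_enforced(self):
        with pytest.raises(ValueError):
            synth.InteractionTruth("a", "b", "suppressor", interaction_shift=1)
        with pytest.raises(ValueError):
            synth.InteractionTruth("a", "b", "additive", interaction_shift=2)
        with pytest.raises(ValueError):
            synth.generate_score_table([], 20.0, seed=0)


class TestExpressionStudy:
    def test_knockdown_gene_passes_the_de_filter(self):
        from flyscreen.enrich import call_de_genes
        study = synth.generate_expression_study(
            synth.ExpressionTruth(n_genes=500, n_models=2, n_de_per_model=20,
                                  seed=0))
        for model, kd in zip(study.truth["models"],
                             study.truth["knockdown_genes"]):
            table = study.de_tables[model]
            row = table[table.gene == kd].iloc[0]
            assert -1.3 <= row.log2FC < -1.0 and row.FDR < 0.05
            assert kd in call_de_genes(table)

    def test_oversized_planted_term_rejected(self):
        with pytest.raises(ValueError):
            synth.ExpressionTruth(n_genes=100, planted_terms=(
                ("t", tuple(synth.gene_ids(200)), 1.0),))

    def test_planted_term_dominates_enrichment(self):
        from flyscreen.enrich import page_zscores
        members = tuple(synth.gene_ids(3000)[-50:])
        wins = 0
        for seed in range(20):
            study = synth.generate_expression_study(synth.ExpressionTruth(
                n_genes=3000, n_models=1, n_de_per_model=30,
                planted_terms=(("planted", members, 2.0),), seed=seed))
            result = page_zscores(study.de_tables["model1"], study.gene_sets)
            top = result.loc[result.Z.abs().idxmax(), "term"]
            wins += top == "planted"
        assert wins >= 19

    def test_determinism(self):
        a = synth.generate_expression_study(synth.ExpressionTruth(
            n_genes=300, n_models=2, n_de_per_model=10, seed=9))
        b = synth.generate_expression_study(synth.ExpressionTruth(
            n_genes=300, n_models=2, n_de_per_model=10, seed=9))
        for model in a.de_tables:
            assert a.de_tables[model].equals(b.de_tables[model])


class TestNetworks:
    def test_three_node_path_truth(self):
        from flyscreen.brainnet import connector_analysis
        import networkx as nx
        graph = nx.Graph()
        graph.add_edges_from([("a", "b", {"weight": 1.0}),
                              ("b", "c", {"weight": 1.0})])
        result = connector_analysis(graph, ["a", "c"])
        assert result.connectors == {"b"}

    def test_annotation_set_is_reproducible_binomial(self):
        net1 = synth.generate_network(500, {"kind": "erdos_renyi", "p": 0.02},
                                      5, 0.1, seed=42)
        net2 = synth.generate_network(500, {"kind": "erdos_renyi", "p": 0.02},
                                      5, 0.1, seed=42)
        assert net1.annotation == net2.annotation
        n = net1.graph.number_of_nodes()
        assert 0.05 * n < len(net1.annotation) < 0.15 * n

    def test_disconnected_graph_falls_back_to_giant_component(self):
        net = synth.generate_network(60, {"kind": "erdos_renyi", "p": 0.03},
                                     3, 0.1, seed=1)
        import networkx as nx
        assert nx.is_connected(net.graph)
        weights = [d["weight"] for _, _, d in net.graph.edges(data=True)]
        assert all(0 < w <= 1 for w in weights)

    def test_impossible_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_network(5, {"kind": "erdos_renyi", "p": 0.5}, 10,
                                   0.1, seed=0)
        with pytest.raises(ValueError):
            synth.generate_network(5, {"kind": "unknown"}, 2, 0.1, seed=0)


def test_child_seeds_are_stable_and_distinct():
    seeds = synth.child_seeds(123, 5)
    assert seeds == synth.child_seeds(123, 5)
    assert len(set(seeds)) == 5
    assert all(0 <= s < 2**31 for s in seeds)
    # prefix stability: adding a generator never perturbs earlier streams
    assert synth.child_seeds(123, 3) == seeds[:3]
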