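"""Embeddings, clustering, gating, light-chain clonality, QC flagging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, silhouette_score

import qbc2 as q


def _clr_from_rows(rows, names):
    features = pd.DataFrame({"name": names, "class": ["marker"] * len(names)})
    cm = q.CountMatrix(sp.csr_matrix(np.asarray(rows)),
                       [f"b{i}" for i in range(len(rows))], features)
    return q.clr_transform(cm)


@pytest.fixture(scope="module")
def gating_clr():
    """One-sample population with a known 84% CD19+CD3- fraction among
    CD45+ cells and a 90% kappa-dominant B compartment."""
    _, cfg = q.fixture_config("ten_patients", seed=33, cells_per_sample=60,
                              ht2_spike_fraction=0.0, ht3_spike_fraction=0.0)
    comp = {"b_kappa": 0.84 * 0.9, "b_lambda": 0.84 * 0.1, "t_cd4": 0.16}
    cfg.sample_sizes = {"p1": 800}
    cfg.sample_composition = {"p1": comp}
    cfg.hashtag_code = q.HashtagCode({"p1": frozenset({"H1"})})
    cells = q.simulate_cells(cfg)
    clr = q.clr_transform(q.counts_from_truth(cells, cfg.panel))
    return clr, cells


class TestPCA:
    def test_first_component_separates_two_populations(self, two_pop_clr):
        clr, labels = two_pop_clr
        emb = q.pca(clr, n_components=3)
        pc1 = emb.coords[:, 0]
        a, b = pc1[labels == "jurkat"], pc1[labels == "hek293t"]
        assert min(a.max(), b.max()) < max(a.min(), b.min())  # disjoint ranges

    def test_loadings_are_orthonormal(self, two_pop_clr):
        emb = q.pca(two_pop_clr[0], n_components=4)
        gram = emb.loadings @ emb.loadings.T
        assert np.allclose(gram, np.eye(4), atol=1e-10)

    def test_explained_variance_is_non_increasing(self, two_pop_clr):
        ev = q.pca(two_pop_clr[0], n_components=5).explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_full_rank_projection_reconstructs_data(self, two_pop_clr):
        clr = two_pop_clr[0]
        k = clr.values.shape[1]
        emb = q.pca(clr, n_components=k)
        centered = clr.values - clr.values.mean(axis=0)
        recon = emb.coords @ emb.loadings
        assert np.allclose(recon, centered, atol=1e-8)

    def test_single_direction_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        clr = q.CLRMatrix(np.outer(t, [1.0, -1.0, 0.0]),
                          [f"b{i}" for i in range(50)],
                          pd.DataFrame({"name": ["a", "b", "c"],
                                        "class": ["marker"] * 3}))
        emb = q.pca(clr, n_components=3)
        assert emb.explained_variance[0] > 1e-6
        assert np.allclose(emb.explained_variance[1:], 0.0, atol=1e-12)

    def test_too_many_components_is_an_error(self, two_pop_clr):
        with pytest.raises(ValueError):
            q.pca(two_pop_clr[0], n_components=99)


class TestKMeans:
    def test_k1_gives_one_cluster(self, two_pop_clr):
        emb = q.pca(two_pop_clr[0], 2)
        labels = q.kmeans_cluster(emb.coords, k=1, seed=0)
        assert len(set(labels)) == 1

    def test_well_separated_blobs_recovered_across_seeds(self):
        _, cfg = q.fixture_config("two_lines", seed=41, n_cells=400,
                                  ht3_spike_fraction=0.0)
        cells = q.simulate_cells(cfg)
        clr = q.clr_transform(q.counts_from_truth(cells, cfg.panel))
        emb = q.pca(clr, 3)
        truth = [c.cell_type for c in cells]
        for seed in range(10):
            labels = q.kmeans_cluster(emb.coords, k=4, seed=seed)
            assert adjusted_rand_score(truth, labels) >= 0.95

    def test_duplicating_points_keeps_the_pattern(self, two_pop_clr):
        emb = q.pca(two_pop_clr[0], 2)
        doubled = np.vstack([emb.coords, emb.coords])
        labels = q.kmeans_cluster(doubled, k=2, seed=3)
        n = emb.coords.shape[0]
        assert (labels[:n] == labels[n:]).all()

    def test_k_exceeding_cells_is_an_error(self):
        with pytest.raises(ValueError):
            q.kmeans_cluster(np.zeros((3, 2)), k=4)


class TestTSNE:
    def test_populations_remain_separated(self, two_pop_clr):
        clr, labels = two_pop_clr
        emb = q.tsne_embed(clr, seed=0, perplexity=20)
        assert silhouette_score(emb.coords, labels) > 0

    def test_same_seed_same_coordinates(self, two_pop_clr):
        a = q.tsne_embed(two_pop_clr[0], seed=1, perplexity=20)
        b = q.tsne_embed(two_pop_clr[0], seed=1, perplexity=20)
        assert np.array_equal(a.coords, b.coords)

    def test_random_init_also_runs(self, two_pop_clr):
        emb = q.tsne_embed(two_pop_clr[0], seed=0, perplexity=20,
                           pca_init=False)
        assert emb.coords.shape[1] == 2

    def test_too_few_cells_is_an_error(self, two_pop_clr):
        with pytest.raises(ValueError):
            q.tsne_embed(two_pop_clr[0], perplexity=1e6)


class TestGating:
    def test_threshold_below_all_scores_keeps_parent(self, two_pop_clr):
        clr = two_pop_clr[0]
        gates = q.gate(clr, "CD45", ">", threshold=-1e9, name="all_cd45")
        assert (gates.mask("all_cd45") == gates.mask("all")).all()
        assert gates.fraction_of_parent("all_cd45") == 1.0

    def test_child_gates_nest(self, gating_clr):
        clr, _ = gating_clr
        # every cell in this fixture is CD45-bright, so the CD45 gate needs
        # an explicit threshold (a 2-means split would find no negatives)
        gates = q.gate(clr, "CD45", ">", threshold=0.0, name="cd45+")
        gates = q.gate(clr, "CD19", ">", parent="cd45+", gates=gates,
                       name="cd19+")
        gates = q.gate(clr, "CD3", "<", parent="cd19+", gates=gates,
                       name="b")
        assert (gates.mask("b") <= gates.mask("cd19+")).all()
        assert (gates.mask("cd19+") <= gates.mask("cd45+")).all()
        report = gates.report()
        assert ((report["fraction_of_parent"] >= 0)
                & (report["fraction_of_parent"] <= 1)).all()

    def test_b_cell_fraction_recovers_generating_parameter(self, gating_clr):
        clr, _ = gating_clr
        gates = q.gate(clr, "CD45", ">", threshold=-1e9, name="cd45+")
        gates = q.gate(clr, "CD19", ">", parent="cd45+", gates=gates,
                       name="cd19+")
        gates = q.gate(clr, "CD3", "<", parent="cd19+", gates=gates, name="b")
        n = int(gates.mask("cd45+").sum())
        frac = gates.entries["b"].count / n
        se = np.sqrt(0.84 * 0.16 / n)
        assert abs(frac - 0.84) <= 3 * se

    def test_unknown_marker_is_an_error(self, two_pop_clr):
        with pytest.raises(ValueError, match="marker"):
            q.gate(two_pop_clr[0], "CD99", ">")


class TestKappaLambda:
    def _toy_clr(self, n_kappa, n_lambda, n_neither=10):
        rows = []
        rows += [[200, 1]] * n_kappa
        rows += [[1, 200]] * n_lambda
        rows += [[1, 1]] * n_neither
        return _clr_from_rows(rows, ["kappa", "lambda"])

    def test_boundary_normal_ratio(self):
        clr = self._toy_clr(60, 30)
        res = q.kappa_lambda_ratio(clr, np.ones(100, dtype=bool),
                                   positivity_threshold=0.0)
        assert res.ratio == pytest.approx(2.0)
        assert res.interpretation == "normal"

    def test_lambda_expansion(self):
        clr = self._toy_clr(30, 60)
        res = q.kappa_lambda_ratio(clr, np.ones(100, dtype=bool),
                                   positivity_threshold=0.0)
        assert res.ratio == pytest.approx(0.5)
        assert res.interpretation == "lambda-expanded"

    def test_zero_lambda_gives_infinite_ratio_with_warning(self):
        clr = self._toy_clr(30, 0)
        with pytest.warns(UserWarning, match="infinite"):
            res = q.kappa_lambda_ratio(clr, np.ones(40, dtype=bool),
                                       positivity_threshold=0.0)
        assert np.isinf(res.ratio)

    def test_cells_outside_the_gate_do_not_matter(self):
        clr = self._toy_clr(40, 20, n_neither=0)
        full = np.ones(60, dtype=bool)
        res_all = q.kappa_lambda_ratio(clr, full, positivity_threshold=0.0)
        # append distractor cells and gate them out
        clr2 = self._toy_clr(40, 20, n_neither=50)
        gate = np.zeros(110, dtype=bool)
        gate[:60] = True
        res_gated = q.kappa_lambda_ratio(clr2, gate, positivity_threshold=0.0)
        assert res_all.ratio == res_gated.ratio

    def test_clonal_b_cell_fixture_is_flagged(self, gating_clr):
        clr, cells = gating_clr
        b_mask = np.array([c.cell_type.startswith("b_") for c in cells])
        res = q.kappa_lambda_ratio(clr, b_mask)
        assert res.ratio > 2
        assert res.interpretation == "kappa-expanded"


class TestFlagNonspecific:
    def test_spiked_isotype_cells_are_found(self):
        _, cfg = q.fixture_config("two_lines", seed=55, n_cells=600,
                                  ht2_spike_fraction=0.0,
                                  ht3_spike_fraction=0.0)
        # 2% non-specifically stained cells
        cfg.sample_composition = {"mix": {"jurkat": 0.49, "hek293t": 0.49,
                                          "nonspecific": 0.02}}
        cells = q.simulate_cells(cfg)
        clr = q.clr_transform(q.counts_from_truth(cells, cfg.panel))
        emb = q.pca(clr, n_components=4)
        mask = q.flag_nonspecific(clr, emb,
                                  control_markers=["IgG1-isotype", "HT3"])
        truth = np.array([c.cell_type == "nonspecific" for c in cells])
        sensitivity = mask[truth].mean()
        assert sensitivity >= 0.9
        flagged_frac = mask.mean()
        assert abs(flagged_frac - truth.mean()) < 0.03

    def test_zero_control_variance_gives_empty_mask(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(80, 4))
        vals[:, 3] = 0.0  # isotype column carries no variation
        clr = q.CLRMatrix(vals, [f"b{i}" for i in range(80)],
                          pd.DataFrame({"name": ["a", "b", "c", "iso"],
                                        "class": ["marker"] * 3
                                        + ["isotype_control"]}))
        emb = q.pca(clr, n_components=3)
        with pytest.warns(UserWarning):
            mask = q.flag_nonspecific(clr, emb, ["iso"],
                                      min_loading_mass=0.2)
        assert not mask.any()

    def test_no_control_markers_is_an_error(self, two_pop_clr):
        clr = two_pop_clr[0]
        with pytest.raises(ValueError):
            q.flag_nonspecific(clr, q.pca(clr, 2), [])
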