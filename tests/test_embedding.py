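import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from genecat.catalog_io import CatalogError, PresenceMatrix
from genecat.embedding import (
    NOISE,
    EmbeddingConfig,
    density_cluster,
    embed_2d,
    lsi_embed,
    run_lsi_pipeline,
    select_model,
    subcluster,
    tfidf_transform,
)
from genecat.synthetic_data import generate_catalog, seven_group_config

from conftest import random_presence

SMALL_GRID = EmbeddingConfig(
    k_grid=(15,),
    n_neighbors_grid=(10,),
    min_dist_grid=(0.1,),
    min_cluster_grid=(20,),
    seed=0,
)


class TestTfidf:
    def test_two_by_two_closed_form(self):
        pm = PresenceMatrix(
            sp.csr_matrix(np.array([[1, 1], [1, 0]], dtype=np.int8)),
            ["s1", "s2"],
            ["g1", "g2"],
        )
        out = tfidf_transform(pm).toarray()
        expected = np.array(
            [
                [0.5 * np.log(1.5), 0.5 * np.log(3.0)],
                [1.0 * np.log(1.5), 0.0],
            ]
        )
        assert np.allclose(out, expected, atol=1e-6)
        assert out[0, 0] == pytest.approx(0.202733, abs=1e-6)
        assert out[0, 1] == pytest.approx(0.549306, abs=1e-6)
        assert out[1, 0] == pytest.approx(0.405465, abs=1e-6)

    def test_single_cell_is_ln_two(self):
        pm = PresenceMatrix(sp.csr_matrix(np.array([[1]], dtype=np.int8)), ["s"], ["g"])
        assert tfidf_transform(pm).toarray()[0, 0] == pytest.approx(np.log(2.0))

    def test_matches_dense_naive_implementation(self, rng):
        for _ in range(25):
            pm = random_presence(rng, n_samples=20, n_genes=50, density=0.25)
            dense = pm.matrix.toarray().astype(float)
            n = dense.shape[0]
            naive = np.zeros_like(dense)
            for i in range(n):
                for j in range(dense.shape[1]):
                    tf = dense[i, j] / dense[i].sum()
                    idf = np.log((n + 1) / dense[:, j].sum())
                    naive[i, j] = tf * idf
            assert np.allclose(tfidf_transform(pm).toarray(), naive, atol=1e-12)

    def test_duplicating_a_row_leaves_other_rows_tf_unchanged(self, rng):
        pm = random_presence(rng, n_samples=6, n_genes=15)
        w1 = tfidf_transform(pm).toarray()
        stacked = PresenceMatrix(
            sp.vstack([pm.matrix, pm.matrix[0]]),
            list(pm.sample_ids) + ["dup"],
            pm.gene_ids,
        )
        w2 = tfidf_transform(stacked).toarray()
        # TF of row 1 is local; only the IDF column scaling moves
        rs1 = pm.matrix[1].toarray().ravel() / pm.row_sums()[1]
        np.testing.assert_allclose(
            w2[1][rs1 > 0] / rs1[rs1 > 0],
            np.log((7 + 1) / stacked.col_sums()[rs1 > 0]),
            atol=1e-12,
        )

    def test_preserves_sparsity_pattern(self, rng):
        pm = random_presence(rng)
        out = tfidf_transform(pm)
        assert ((out != 0).astype(int) != pm.matrix.astype(int)).nnz == 0


class TestLsiEmbed:
    def test_rank_one_matrix_exact_with_one_component(self):
        u = np.outer([1, 2, 3, 4.0], [1, 0.5, 0.25])
        scores = lsi_embed(sp.csr_matrix(u), k=1, seed=0)
        recon = np.linalg.norm(u) - np.linalg.norm(scores)
        assert abs(recon) <= 1e-8

    def test_block_diagonal_scores_separate_blocks(self, rng):
        a = rng.random((10, 20))
        block = sp.block_diag([a, a]).tocsr()
        scores = lsi_embed(block, k=2, seed=0)
        d_within = np.linalg.norm(scores[0] - scores[5])
        d_between = np.linalg.norm(scores[0] - scores[15])
        assert d_between > 5 * d_within or d_within < 1e-8

    def test_invalid_k_rejected(self, rng):
        pm = random_presence(rng, n_samples=10, n_genes=30)
        with pytest.raises(CatalogError, match="k="):
            lsi_embed(tfidf_transform(pm), k=10)


class TestEmbed2d:
    def test_separated_blobs_stay_separable(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.3, (60, 5)), rng.normal(8, 0.3, (60, 5))]
        )
        coords = embed_2d(X, n_neighbors=10, min_dist=0.1, seed=0)
        from sklearn.linear_model import LogisticRegression

        y = np.repeat([0, 1], 60)
        acc = LogisticRegression().fit(coords, y).score(coords, y)
        assert acc == 1.0

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 6))
        c1 = embed_2d(X, 10, 0.1, seed=3)
        c2 = embed_2d(X, 10, 0.1, seed=3)
        assert np.array_equal(c1, c2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(CatalogError, match="n_neighbors"):
            embed_2d(rng.normal(size=(5, 3)), n_neighbors=10, min_dist=0.1)


class TestDensityCluster:
    def test_two_blobs_recovered_exactly(self, rng):
        coords = np.vstack(
            [rng.normal(0, 0.5, (500, 2)), rng.normal(10, 0.5, (500, 2))]
        )
        labels = density_cluster(coords, min_cluster_size=50)
        truth = np.repeat([0, 1], 500)
        assert len(set(labels) - {NOISE}) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_sparse_scatter_is_all_noise(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        labels = density_cluster(coords, min_cluster_size=50)
        assert set(labels) == {NOISE}

    def test_invariant_to_point_order(self, rng):
        coords = np.vstack(
            [rng.normal(0, 0.5, (100, 2)), rng.normal(10, 0.5, (100, 2))]
        )
        labels = density_cluster(coords, 25)
        perm = rng.permutation(len(coords))
        labels_p = density_cluster(coords[perm], 25)
        assert adjusted_rand_score(labels, labels_p[np.argsort(perm)]) == 1.0


class TestSelectModel:
    @staticmethod
    def _grid(rows):
        cols = ["k", "n_neighbors", "min_dist", "min_cluster_size",
                "silhouette", "n_clusters", "n_unclustered", "n_samples"]
        return pd.DataFrame(rows, columns=cols)

    def test_dominant_cell_wins(self):
        grid = self._grid(
            [
                [10, 10, 0.1, 25, 0.9, 3, 1, 100],
                [50, 10, 0.1, 25, 0.5, 3, 2, 100],
            ]
        )
        assert select_model(grid)["k"] == 10

    def test_tie_breaks_toward_fewer_unclustered(self):
        grid = self._grid(
            [
                [10, 10, 0.1, 25, 0.7, 3, 50, 1000],
                [50, 10, 0.1, 25, 0.7, 3, 10, 1000],
            ]
        )
        assert select_model(grid, noise_fraction_max=0.10)["k"] == 50

    def test_noise_cap_relaxes_to_minimum_when_unreachable(self):
        grid = self._grid(
            [
                [10, 10, 0.1, 25, 0.9, 3, 400, 1000],
                [50, 10, 0.1, 25, 0.3, 3, 200, 1000],
            ]
        )
        assert select_model(grid, noise_fraction_max=0.10)["k"] == 50

    def test_undefined_silhouette_never_beats_defined(self):
        grid = self._grid(
            [
                [10, 10, 0.1, 25, np.nan, 1, 0, 100],
                [50, 10, 0.1, 25, 0.2, 2, 5, 100],
            ]
        )
        assert select_model(grid)["k"] == 50

    def test_matches_exhaustive_scan_oracle(self, rng):
        rows = []
        for k in (10, 50):
            for nn in (10, 15):
                for md in (0.1, 0.25):
                    for mcs in (25, 50):
                        rows.append(
                            [k, nn, md, mcs,
                             float(np.round(rng.random(), 2)),
                             int(rng.integers(1, 5)),
                             int(rng.integers(0, 200)), 1000]
                        )
        grid = self._grid(rows)
        chosen = select_model(grid, noise_fraction_max=0.10)
        # brute-force re-derivation of the stated lexicographic rule
        df = grid.assign(nf=grid.n_unclustered / grid.n_samples)
        ok = df[df.nf <= 0.10]
        if ok.empty:
            ok = df[df.nf <= df.nf.min() + 1e-12]
        defined = ok[ok.silhouette.notna()]
        if len(defined):
            ok = defined[defined.silhouette == defined.silhouette.max()]
        best = ok.sort_values(
            ["n_unclustered", "min_cluster_size", "k", "n_neighbors", "min_dist"]
        ).iloc[0]
        assert chosen == {
            "k": int(best.k),
            "n_neighbors": int(best.n_neighbors),
            "min_dist": float(best.min_dist),
            "min_cluster_size": int(best.min_cluster_size),
        }


@pytest.fixture(scope="module")
def seven_catalog():
    cfg = seven_group_config(n_samples=40, seed=3, singleton_target=0.5)
    return generate_catalog(cfg)


class TestPipeline:
    def test_recovers_seven_planted_groups(self, seven_catalog):
        st, pm, _, truth = seven_catalog
        res = run_lsi_pipeline(pm, SMALL_GRID)
        assert res.n_clusters == 7
        truth_labels = st.aligned_to(res.sample_ids).df["ecology_group"].to_numpy()
        mask = res.labels != NOISE
        assert adjusted_rand_score(truth_labels[mask], res.labels[mask]) >= 0.9
        assert -1 <= res.silhouette <= 1
        assert res.n_unclustered == int((res.labels == NOISE).sum())

    def test_rerun_same_seed_identical(self, seven_catalog):
        _, pm, _, _ = seven_catalog
        r1 = run_lsi_pipeline(pm, SMALL_GRID)
        r2 = run_lsi_pipeline(pm, SMALL_GRID)
        assert np.array_equal(r1.coords, r2.coords)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.chosen_params == r2.chosen_params

    def test_grid_report_is_consistent(self, seven_catalog):
        _, pm, _, _ = seven_catalog
        cfg = EmbeddingConfig(
            k_grid=(15,), n_neighbors_grid=(10,), min_dist_grid=(0.1,),
            min_cluster_grid=(20, 40), seed=0,
        )
        res = run_lsi_pipeline(pm, cfg)
        assert len(res.grid_report) == 2
        sils = res.grid_report["silhouette"].dropna()
        assert ((sils >= -1) & (sils <= 1)).all()

    def test_metadata_overlay_contains_host_facets(self, seven_catalog):
        st, pm, _, _ = seven_catalog
        res = run_lsi_pipeline(pm, SMALL_GRID)
        df = res.to_frame(st)
        assert {"westernized", "age_category", "ecology", "disease_status"} <= set(df.columns)
        assert len(df) == pm.n_samples


class TestSubcluster:
    def test_whole_data_cluster_equals_full_pipeline(self, rng):
        cfg = seven_group_config(n_samples=30, seed=5, singleton_target=0.4)
        st, pm, _, _ = generate_catalog(cfg)
        parent = run_lsi_pipeline(pm, SMALL_GRID)
        # treat all samples as one parent cluster covering the data
        parent.labels = np.zeros(pm.n_samples, dtype=int)
        sub_cfg = EmbeddingConfig(
            k_grid=(15,), n_neighbors_grid=(10,), min_dist_grid=(0.1,),
            min_cluster_grid=(20,), seed=0,
        )
        sub = subcluster(pm, st, parent, [0], cfg=sub_cfg)[0]
        full = run_lsi_pipeline(pm, sub_cfg)
        assert np.array_equal(sub.labels, full.labels)
        assert np.array_equal(sub.coords, full.coords)

    def test_nested_structure_recovered_within_parent_cluster(self):
        # a group-level parent cluster containing two sub-ecologies:
        # re-embedding only its member samples splits the two
        from genecat.synthetic_data import EcologySpec, GeneratorConfig

        ecologies = (
            EcologySpec("sub0", "groupA", 60, (80, 120), core_frac=0.7),
            EcologySpec("sub1", "groupA", 60, (80, 120), core_frac=0.7),
            EcologySpec("other", "groupB", 60, (80, 120)),
        )
        cfg = GeneratorConfig(
            ecologies=ecologies,
            n_conserved=20,
            default_core_size=150,
            default_specific_size=120,
            singleton_target=0.3,
            seed=4,
        )
        st, pm, _, _ = generate_catalog(cfg)
        parent = run_lsi_pipeline(pm, SMALL_GRID)
        # planted parent assignment at group level
        groups = st.aligned_to(parent.sample_ids).df["ecology_group"].to_numpy()
        parent.labels = np.where(groups == "groupA", 0, 1)
        sub_cfg = EmbeddingConfig(
            k_grid=(10,), n_neighbors_grid=(10,), min_dist_grid=(0.1,),
            min_cluster_grid=(25,), seed=0,
        )
        sub = subcluster(pm, st, parent, [0], cfg=sub_cfg)[0]
        assert sub.n_clusters == 2
        assert set(sub.sample_ids) == set(parent.sample_ids[groups == "groupA"])
        truth = st.aligned_to(sub.sample_ids).df["ecology"].to_numpy()
        mask = sub.labels != NOISE
        assert adjusted_rand_score(truth[mask], sub.labels[mask]) >= 0.9

    def test_undersized_cluster_error_names_it(self, rng):
        cfg = seven_group_config(n_samples=30, seed=6, singleton_target=0.4)
        st, pm, _, _ = generate_catalog(cfg)
        parent = run_lsi_pipeline(pm, SMALL_GRID)
        parent.labels = np.zeros(pm.n_samples, dtype=int)
        parent.labels[:5] = 9
        with pytest.raises(CatalogError, match="cluster 9"):
            subcluster(pm, st, parent, [9])
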