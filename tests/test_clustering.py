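"""Correlation, PCA, PAM/CLARA and silhouette machinery.

PAM is validated against exhaustive medoid-set enumeration; CLARA against
its PAM reduction; the planted-block pipeline against scikit-learn's ARI.
"""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

import chemocoex as cc
from chemocoex.clustering import ClusteringError, pam, silhouette_width
from chemocoex.simulate import block_labels

from conftest import make_matrix


def exhaustive_pam_cost(d: np.ndarray, k: int) -> float:
    """Optimal k-medoid cost by enumerating all medoid subsets."""
    n = d.shape[0]
    return min(
        d[np.ix_(meds, range(n))].min(axis=0).sum() for meds in combinations(range(n), k)
    )


def line_dissimilarity(points):
    x = np.asarray(points, dtype=float)[:, None]
    return squareform(pdist(x))


class TestPearsonMatrix:
    def test_duplicated_gene_has_r_one_negation_minus_one(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        m = make_matrix(np.vstack([base, base, -base]))
        r = cc.pearson_matrix(m)
        assert r.loc["g1", "g2"] == pytest.approx(1.0)
        assert r.loc["g1", "g3"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0], [0.0, 1.0, 0.0]]))
        r = cc.pearson_matrix(m)
        assert r.loc["g1", "g2"] == pytest.approx(0.98198, abs=1e-5)

    def test_diagonal_symmetry_and_range(self, filtered_matrix):
        r = cc.pearson_matrix(filtered_matrix)
        assert np.allclose(np.diag(r.to_numpy()), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert (r.to_numpy() >= -1).all() and (r.to_numpy() <= 1).all()

    def test_positive_semidefinite(self, filtered_matrix):
        r = cc.pearson_matrix(filtered_matrix)
        assert np.linalg.eigvalsh(r.to_numpy()).min() >= -1e-8

    def test_zero_variance_gene_dropped_with_warning(self, caplog):
        m = make_matrix(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 1.0, 4.0]]))
        with caplog.at_level("WARNING"):
            r = cc.pearson_matrix(m)
        assert "g2" not in r.index and "zero-variance" in caplog.text

    def test_too_few_assays_rejected(self):
        with pytest.raises(ClusteringError, match="3 assays"):
            cc.pearson_matrix(make_matrix(np.random.default_rng(0).normal(size=(4, 2))))


class TestPca:
    def test_rank_one_data_explained_by_pc1(self):
        t = np.arange(5.0)
        m = make_matrix(np.outer(t, [1.0, 2.0, 3.0]))
        res = cc.pca_scores(m, m=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_orthogonal_variance_directions(self):
        """Columns with variances 4 and 1 give explained fractions 0.8/0.2."""
        a = np.repeat([-1.0, 1.0], 50)
        b = np.tile([-1.0, 1.0], 50)
        x = np.column_stack([2 * a, b])  # orthogonal directions, variance ratio 4:1
        res = cc.pca_scores(make_matrix(x), m=2)
        assert res.explained_variance_ratio == pytest.approx([0.8, 0.2], abs=1e-6)

    def test_loadings_orthogonal(self, filtered_matrix):
        res = cc.pca_scores(filtered_matrix, m=3)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_matches_sklearn_scores(self, filtered_matrix):
        """Cross-check coordinates against scikit-learn's PCA up to sign."""
        res = cc.pca_scores(filtered_matrix, m=2)
        sk = SkPCA(n_components=2).fit_transform(filtered_matrix.values.to_numpy())
        for j in range(2):
            ours = res.scores.iloc[:, j].to_numpy()
            assert np.allclose(ours, sk[:, j], atol=1e-8) or np.allclose(
                ours, -sk[:, j], atol=1e-8
            )

    def test_m_too_large_rejected(self):
        with pytest.raises(ClusteringError):
            cc.pca_scores(make_matrix(np.ones((3, 3)) + np.eye(3)), m=4)


class TestStandardizeGenes:
    def test_two_point_row_uses_sample_sd(self):
        z = cc.standardize_genes(make_matrix(np.array([[0.0, 2.0], [1.0, 5.0]])))
        assert z.values.loc["g1"].to_numpy() == pytest.approx([-0.7071067, 0.7071067])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        z1 = cc.standardize_genes(make_matrix(rng.normal(size=(5, 8))))
        z2 = cc.standardize_genes(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_distance_correlation_identity(self):
        """For z-scored rows, squared Euclidean distance = 2(n-1)(1-r)."""
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(6, 20)))
        z = cc.standardize_genes(m)
        r = cc.pearson_matrix(m).to_numpy()
        d2 = squareform(pdist(z.values.to_numpy())) ** 2
        assert np.allclose(d2, 2 * (20 - 1) * (1 - r), atol=1e-8)

    def test_zero_variance_gene_named_in_error(self):
        with pytest.raises(ClusteringError, match="g2"):
            cc.standardize_genes(make_matrix(np.array([[0.0, 1.0], [3.0, 3.0]])))


class TestPam:
    def test_two_separated_pairs_on_a_line(self):
        d = line_dissimilarity([0, 1, 10, 11])
        out = pam(d, 2)
        assert out.total_dissimilarity == pytest.approx(2.0)
        assert set(out.labels) == {1, 2}

    def test_k_equals_n_zero_cost(self):
        d = line_dissimilarity([0, 3, 7, 20])
        out = pam(d, 4)
        assert out.total_dissimilarity == 0.0
        assert set(out.medoids) == set(out.items)

    def test_duplicated_points_k1_medoid_is_copy_of_original_medoid(self):
        pts = [0.0, 1.0, 5.0]
        single = pam(line_dissimilarity(pts), 1)
        doubled = pam(line_dissimilarity(pts + pts), 1)
        best = single.medoids[0]
        assert doubled.medoids[0] in {best, str(int(best) + 3)}

    def test_k1_build_is_exhaustively_optimal(self):
        """For k=1 the BUILD step is exactly the exhaustive 1-medoid."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 11))
            d = squareform(pdist(rng.normal(size=(n, 2))))
            assert pam(d, 1).total_dissimilarity == pytest.approx(
                exhaustive_pam_cost(d, 1), abs=1e-9
            )

    @pytest.mark.parametrize("k", [2, 3])
    def test_solution_is_swap_local_optimal(self, k):
        """No single (medoid, non-medoid) exchange improves the returned
        solution — the convergence guarantee of the SWAP phase."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(max(k, 4), 11))
            d = squareform(pdist(rng.normal(size=(n, 2))))
            out = pam(d, k)
            meds = [int(m) for m in out.medoids]
            cur = out.total_dissimilarity
            for mi in range(k):
                for h in range(n):
                    if h in meds:
                        continue
                    trial = meds.copy()
                    trial[mi] = h
                    cost = d[np.ix_(trial, range(n))].min(axis=0).sum()
                    assert cost >= cur - 1e-9

    def test_matches_reference_r_implementation(self, tmp_path):
        """Cost agrees with R's cluster::pam (the canonical BUILD+SWAP
        implementation) on random Euclidean instances."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(17)
        instances = [rng.normal(size=(int(rng.integers(6, 12)), 2)) for _ in range(8)]
        script = tmp_path / "pam.R"
        script.write_text(
            "library(cluster)\n"
            "args <- commandArgs(trailingOnly=TRUE)\n"
            "x <- as.matrix(read.table(args[1]))\n"
            "p <- pam(x, as.integer(args[2]))\n"
            "d <- as.matrix(dist(x))\n"
            "cat(sprintf('%.12f', sum(apply(d[p$id.med,,drop=FALSE], 2, min))))\n"
        )
        for i, x in enumerate(instances):
            k = 2 + i % 2
            pts = tmp_path / f"pts{i}.txt"
            np.savetxt(pts, x)
            r_out = subprocess.run(
                ["Rscript", str(script), str(pts), str(k)],
                capture_output=True,
                text=True,
                check=True,
            )
            ours = pam(squareform(pdist(x)), k).total_dissimilarity
            assert ours == pytest.approx(float(r_out.stdout.strip()), abs=1e-8)

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.normal(size=(12, 3))))
        out = pam(d, 3)
        for j, m in enumerate(out.medoids, start=1):
            assert m in out.members(j)

    def test_bad_k_rejected(self):
        d = line_dissimilarity([0, 1, 2])
        for k in (0, 4):
            with pytest.raises(ClusteringError):
                pam(d, k)


class TestClara:
    def test_full_sample_reduces_to_pam(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            x = rng.normal(size=(15, 4))
            m = make_matrix(x)
            d = squareform(pdist(x))
            full = pam(d, 3, items=tuple(m.values.index))
            cl = cc.clara(m, 3, n_samples=1, sample_size=15, seed=seed)
            assert cl.medoids == full.medoids
            assert np.array_equal(cl.labels, full.labels)

    def test_separated_clouds_split_perfectly(self):
        rng = np.random.default_rng(0)
        x = np.vstack(
            [rng.normal(-10, 0.1, size=(10, 3)), rng.normal(10, 0.1, size=(10, 3))]
        )
        out = cc.clara(make_matrix(x), 2, seed=1)
        labels = out.labels
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_recovers_planted_blocks(self, panel, lr_panel):
        """On the default synthetic corpus the three planted co-expression
        blocks are recovered essentially perfectly (ARI vs ground truth)."""
        cfg = cc.default_corpus_config(panel, seed=3)
        corpus = cc.generate_corpus(cfg)
        filtered, _ = cc.four_step_filter(cc.assemble_matrix(corpus, lr_panel))
        z = cc.standardize_genes(filtered)
        out = cc.clara(z, 3, seed=3)
        truth = block_labels(cfg)
        assert adjusted_rand_score([truth[g] for g in out.items], out.labels) >= 0.9

    def test_sample_size_below_k_rejected(self):
        with pytest.raises(ClusteringError):
            cc.clara(make_matrix(np.random.default_rng(0).normal(size=(10, 3))), 4, sample_size=3)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        """Points 0,1,10,11 in clusters {0,1},{10,11}: outer points have
        a=1, b=10.5 (s=9.5/10.5), inner points a=1, b=9.5 (s=8.5/9.5);
        mean = 0.899749..."""
        d = line_dissimilarity([0, 1, 10, 11])
        out = pam(d, 2)
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert silhouette_width(out, d) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(30, 4))
        d = squareform(pdist(x))
        out = pam(d, 3)
        ours = silhouette_width(out, d)
        theirs = silhouette_score(d, out.labels, metric="precomputed")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_far_separated_tight_clusters_approach_one(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(1000, 1, 20)])[:, None]
        d = squareform(pdist(x))
        out = pam(d, 2)
        assert silhouette_width(out, d) >= 0.99

    def test_random_labels_on_structureless_data_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 5))
        d = squareform(pdist(x))
        labels = rng.integers(1, 3, size=200)
        fake = cc.ClusterAssignment(
            items=tuple(map(str, range(200))),
            labels=labels,
            medoids=("0", "1"),
            total_dissimilarity=0.0,
        )
        assert abs(silhouette_width(fake, d)) < 0.1

    def test_single_cluster_rejected(self):
        d = line_dissimilarity([0, 1, 2])
        one = pam(d, 1)
        with pytest.raises(ClusteringError):
            silhouette_width(one, d)


class TestSelectK:
    def test_finds_three_planted_blocks(self, filtered_matrix):
        z = cc.standardize_genes(filtered_matrix)
        k, table = cc.select_k(z, range(2, 7), seed=1)
        assert k == 3
        assert list(table["k"]) == [2, 3, 4, 5, 6]

    def test_two_separated_clouds_give_k2(self):
        rng = np.random.default_rng(0)
        x = np.vstack(
            [rng.normal(-10, 0.1, size=(12, 3)), rng.normal(10, 0.1, size=(12, 3))]
        )
        k, _ = cc.select_k(make_matrix(x), range(2, 6), seed=2)
        assert k == 2

    def test_deterministic_under_fixed_seed(self, filtered_matrix):
        z = cc.standardize_genes(filtered_matrix)
        k1, t1 = cc.select_k(z, range(2, 5), seed=5)
        k2, t2 = cc.select_k(z, range(2, 5), seed=5)
        assert k1 == k2 and t1.equals(t2)

    def test_empty_range_rejected(self, filtered_matrix):
        with pytest.raises(ClusteringError):
            cc.select_k(cc.standardize_genes(filtered_matrix), [])


class TestHclustOrder:
    def test_perfectly_correlated_genes_adjacent(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        rows = [base, rng.normal(size=10), base * 2 + 1, rng.normal(size=10)]
        corr = cc.pearson_matrix(make_matrix(np.array(rows)))
        order = cc.hclust_order(corr)
        assert abs(order.index("g1") - order.index("g3")) == 1

    def test_block_structure_contiguous(self):
        """Two planted correlation blocks appear as contiguous runs."""
        rng = np.random.default_rng(3)
        z1, z2 = rng.normal(size=50), rng.normal(size=50)
        rows = [z1 + 0.1 * rng.normal(size=50) for _ in range(3)] + [
            z2 + 0.1 * rng.normal(size=50) for _ in range(3)
        ]
        corr = cc.pearson_matrix(make_matrix(np.array(rows)))
        order = cc.hclust_order(corr)
        positions = {g: i for i, g in enumerate(order)}
        first = sorted(positions[g] for g in ["g1", "g2", "g3"])
        assert first in ([0, 1, 2], [3, 4, 5])

    def test_order_is_permutation(self, filtered_matrix):
        corr = cc.pearson_matrix(filtered_matrix)
        order = cc.hclust_order(corr)
        assert sorted(order) == sorted(corr.index)
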