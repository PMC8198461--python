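import itertools

import numpy as np
import pandas as pd
import pytest

from thyrosig import (
    ExpressionMatrix,
    GeneSignature,
    MergedDataset,
    cluster_agreement,
    merge_and_standardize,
    merge_common,
    pca_project,
    ward_cluster,
    zscore_by_dataset,
)


def _expr(rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


class TestZscore:
    def test_hand_oracle_sample_sd(self):
        expr = _expr({"g": [2.0, 4.0, 6.0]}, ["s1", "s2", "s3"])
        batch = pd.Series(["b1"] * 3, index=["s1", "s2", "s3"])
        out = zscore_by_dataset(expr, batch)
        np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped_everywhere(self):
        expr = _expr(
            {"g1": [1.0, 2.0, 3.0, 4.0], "g2": [5.0, 5.0, 1.0, 2.0]},
            ["a1", "a2", "b1", "b2"],
        )
        batch = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        out = zscore_by_dataset(expr, batch)
        assert out.gene_ids == ["g1"]

    def test_per_batch_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(7)]
        df = pd.DataFrame(
            rng.normal(8, 2, size=(30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=samples,
        )
        batch = pd.Series(["A"] * 5 + ["B"] * 7, index=samples)
        out = zscore_by_dataset(ExpressionMatrix(df), batch)
        for label in ("A", "B"):
            block = out.data[batch.index[batch == label]]
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_singleton_batch_rejected(self):
        expr = _expr({"g": [1.0, 2.0, 3.0]}, ["s1", "s2", "s3"])
        batch = pd.Series(["A", "A", "B"], index=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="single sample"):
            zscore_by_dataset(expr, batch)


class TestMergeCommon:
    def test_intersection_sorted(self):
        a = _expr({"A": [1, 2], "C": [3, 4], "B": [5, 6]}, ["x1", "x2"])
        b = _expr({"B": [1, 2], "C": [3, 4], "D": [5, 6]}, ["y1", "y2"])
        merged, batch = merge_common(a, b)
        assert merged.gene_ids == ["B", "C"]
        assert merged.sample_ids == ["x1", "x2", "y1", "y2"]
        assert batch.tolist() == ["a", "a", "b", "b"]

    def test_disjoint_universes_error(self):
        a = _expr({"A": [1, 2]}, ["x1", "x2"])
        b = _expr({"B": [1, 2]}, ["y1", "y2"])
        with pytest.raises(ValueError, match="share no genes"):
            merge_common(a, b)

    def test_sample_collision_error(self):
        a = _expr({"A": [1, 2]}, ["s1", "s2"])
        b = _expr({"A": [1, 2]}, ["s1", "s3"])
        with pytest.raises(ValueError, match="both datasets"):
            merge_common(a, b)

    def test_full_overlap_keeps_whole_universe(self, planted, cohort):
        _, _, cells, _ = planted
        _, _, tissues, _ = cohort
        merged, _ = merge_common(cells, tissues)
        assert len(merged.gene_ids) == len(cells.gene_ids)


def _merged(values: np.ndarray, samples: list[str], genes: list[str]) -> MergedDataset:
    df = pd.DataFrame(values, index=genes, columns=samples)
    return MergedDataset(
        values=df,
        batch=pd.Series(["d"] * len(samples), index=samples),
        group=pd.Series(["g"] * len(samples), index=samples),
    )


class TestWardCluster:
    @staticmethod
    def _exhaustive_best_partition(points: np.ndarray) -> frozenset:
        """Minimum total within-cluster sum of squares over all 2-partitions."""
        n = len(points)
        best, best_cost = None, np.inf
        for size in range(1, n // 2 + 1):
            for left in itertools.combinations(range(n), size):
                right = tuple(i for i in range(n) if i not in left)
                cost = 0.0
                for part in (left, right):
                    block = points[list(part)]
                    cost += ((block - block.mean(axis=0)) ** 2).sum()
                if cost < best_cost:
                    best_cost, best = cost, frozenset([frozenset(left), frozenset(right)])
        return best

    def test_two_tight_pairs_recovered_and_match_exhaustive_oracle(self):
        points = np.array([[0.0, 0.1], [0.1, 0.0], [5.0, 5.1], [5.1, 5.0]])
        data = _merged(points.T, ["s0", "s1", "s2", "s3"], ["g1", "g2"])
        labels = ward_cluster(data).labels(2)
        found = frozenset(
            frozenset(i for i in range(4) if labels.iloc[i] == c)
            for c in set(labels)
        )
        assert found == self._exhaustive_best_partition(points)
        assert found == frozenset([frozenset({0, 1}), frozenset({2, 3})])

    def test_identical_samples_merge_at_height_zero(self):
        points = np.ones((3, 2))
        data = _merged(points.T, ["s0", "s1", "s2"], ["g1", "g2"])
        result = ward_cluster(data)
        np.testing.assert_allclose(result.heights, 0.0)

    def test_merge_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(12, 5))
        data = _merged(points.T, [f"s{i}" for i in range(12)], [f"g{i}" for i in range(5)])
        h = ward_cluster(data).heights
        assert (np.diff(h) >= -1e-12).all()

    def test_cut_larger_than_n_rejected(self):
        points = np.random.default_rng(0).normal(size=(3, 2))
        data = _merged(points.T, ["s0", "s1", "s2"], ["g1", "g2"])
        with pytest.raises(ValueError, match="3 samples"):
            ward_cluster(data).labels(4)

    def test_restrict_requires_two_present_genes(self):
        points = np.random.default_rng(0).normal(size=(3, 4))
        data = _merged(points.T, ["s0", "s1", "s2"], ["g1", "g2", "g3", "g4"])
        sig = GeneSignature.from_genes("S", ["g1", "absent"])
        with pytest.raises(ValueError, match="need >= 2"):
            ward_cluster(data, restrict=sig)


class TestPCA:
    def test_variance_on_one_gene_gives_pc1_everything(self):
        values = np.zeros((3, 6))
        values[0] = [0, 1, 2, 3, 4, 5]
        data = _merged(values, [f"s{i}" for i in range(6)], ["g1", "g2", "g3"])
        res = pca_project(data)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_projection_preserves_pairwise_distances(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 6))
        data = _merged(values, [f"s{i}" for i in range(6)], [f"g{i}" for i in range(4)])
        res = pca_project(data)
        coords = res.coordinates.to_numpy()
        original = values.T
        for i in range(6):
            for j in range(i):
                d_pca = np.linalg.norm(coords[i] - coords[j])
                d_orig = np.linalg.norm(original[i] - original[j])
                assert d_pca == pytest.approx(d_orig)

    def test_explained_variance_nonincreasing_and_sums_to_one(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(10, 8))
        data = _merged(values, [f"s{i}" for i in range(8)], [f"g{i}" for i in range(10)])
        evr = pca_project(data).explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() == pytest.approx(1.0)

    def test_degenerate_zero_variance_rejected(self):
        data = _merged(np.ones((3, 4)), [f"s{i}" for i in range(4)], ["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="degenerate"):
            pca_project(data)


class TestClusterAgreement:
    def test_relabel_invariance(self):
        assert cluster_agreement([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_identical_labelings(self):
        assert cluster_agreement(["a", "a", "b"], ["a", "a", "b"]) == pytest.approx(1.0)

    def test_maximally_discordant_two_class_value(self):
        # contingency-table ARI formula on (0,0,1,1) vs (0,1,0,1): all n_ij=1
        # so sum C(n_ij,2)=0, expected = 2*2/6, max = 2 -> ARI = -0.5
        assert cluster_agreement([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cluster_agreement([0, 1], [0, 1, 2])


class TestEndToEndIntegration:
    def test_treated_cells_cocluster_with_ras_like_tissues(self, planted, cohort):
        """Merged z-scored data cut at k=2 on the BRS signature separates
        {treated + RAS-like} from {DMSO + BRAF-like} perfectly, and treated
        cells sit closer to the RAS-like centroid in the PC1-PC2 plane."""
        config, sigs, cells, cells_ann = planted
        _, _, tissues, tissues_ann = cohort
        brs = sigs[2]
        merged = merge_and_standardize(cells, cells_ann, tissues, tissues_ann)
        labels = ward_cluster(merged, restrict=brs).labels(2)
        rasward = merged.group.isin(["Vemurafenib", "Dabrafenib", "RAS-like"])
        assert cluster_agreement(labels, rasward) == pytest.approx(1.0)

        pca = pca_project(merged, restrict=brs)
        coords = pca.coordinates[["PC1", "PC2"]]
        ras_centroid = coords[merged.group == "RAS-like"].mean()
        for grp, closer in (("Vemurafenib", True), ("Dabrafenib", True)):
            treated_d = np.linalg.norm(
                coords[merged.group == grp] - ras_centroid, axis=1
            ).mean()
            dmso_d = np.linalg.norm(
                coords[merged.group == "DMSO"] - ras_centroid, axis=1
            ).mean()
            assert (treated_d < dmso_d) == closer

    def test_within_batch_standardization_after_merge(self, planted, cohort):
        _, _, cells, cells_ann = planted
        _, _, tissues, tissues_ann = cohort
        merged = merge_and_standardize(cells, cells_ann, tissues, tissues_ann)
        for label in ("cell_lines", "tissues"):
            cols = merged.batch.index[merged.batch == label]
            block = merged.values[cols]
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-10)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-10)
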