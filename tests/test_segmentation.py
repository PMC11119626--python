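import numpy as np
import pytest

from spotsom.segmentation import (
    correlation_cluster_segmentation,
    distance_map,
    dmap_segmentation,
    kmeans_segmentation,
    module_spatial_score,
    overexpression_modules,
)
from spotsom.som import Portrait
from spotsom.types import DataError

from conftest import model_from_weights


def portrait_from(values):
    return Portrait(np.asarray(values, dtype=float), subject="t", kind="group_mean")


def grid_model(rows=6, cols=6, n_spots=4, seed=0):
    rng = np.random.default_rng(seed)
    return model_from_weights(rng.normal(size=(rows, cols, n_spots)))


class TestOverexpression:
    def test_single_plateau_yields_one_module(self):
        # plateau is < 10% of the grid so the 0.9-quantile cut also isolates it
        model = grid_model(rows=10, cols=10)
        values = np.zeros((10, 10))
        values[1:4, 2:5] = 5.0  # 3x3 plateau
        for kwargs in ({}, {"threshold_quantile": 0.9}):
            ms = overexpression_modules(model, [portrait_from(values)], **kwargs)
            assert len(ms) == 1
            assert ms.modules[0].units == frozenset(
                (r, c) for r in range(1, 4) for c in range(2, 5)
            )

    def test_quantile_near_one_gives_empty_set(self):
        model = grid_model()
        rng = np.random.default_rng(1)
        # in the q -> 1 limit at most the single top unit survives the cut,
        # which falls below the default min_units and leaves no module
        ms = overexpression_modules(
            model, [portrait_from(rng.normal(size=(6, 6)))],
            threshold_quantile=1 - 1e-12,
        )
        assert len(ms) == 0

    def test_two_disjoint_plateaus_recovered_exactly(self):
        model = grid_model()
        values = np.zeros((6, 6))
        values[0:2, 0:2] = 4.0
        values[4:6, 4:6] = 6.0
        ms = overexpression_modules(model, [portrait_from(values)])
        masks = {m.units for m in ms}
        assert masks == {
            frozenset((r, c) for r in range(2) for c in range(2)),
            frozenset((r, c) for r in range(4, 6) for c in range(4, 6)),
        }

    def test_gene_lists_come_from_assignment(self):
        model = grid_model()
        values = np.zeros((6, 6))
        values[0:2, 0:2] = 1.0
        ms = overexpression_modules(model, [portrait_from(values)])
        assert sorted(ms.modules[0].gene_ids) == sorted(
            f"g_r{r}c{c}_0" for r in range(2) for c in range(2)
        )

    def test_underexpression_flips_sign(self):
        model = grid_model()
        values = np.zeros((6, 6))
        values[2:4, 2:4] = -9.0
        ms = overexpression_modules(model, [portrait_from(values)], underexpression=True)
        assert len(ms) == 1
        assert ms.modules[0].units == frozenset((r, c) for r in range(2, 4) for c in range(2, 4))
        assert ms.method == "underexpression"

    def test_raising_quantile_never_enlarges_modules(self):
        model = grid_model()
        rng = np.random.default_rng(2)
        portrait = portrait_from(rng.normal(size=(6, 6)))
        prev_union = None
        for q in (0.5, 0.7, 0.9, 0.97):
            ms = overexpression_modules(model, [portrait], threshold_quantile=q, min_units=1)
            union = set().union(*(m.units for m in ms)) if len(ms) else set()
            if prev_union is not None:
                assert union <= prev_union
            prev_union = union

    def test_labels_ordered_by_decreasing_size(self):
        model = grid_model()
        values = np.zeros((6, 6))
        values[0:3, 0:3] = 2.0   # 9 units
        values[5:6, 0:4] = 2.0   # 4 units
        ms = overexpression_modules(model, [portrait_from(values)])
        assert ms.labels == ["A", "B"]
        assert len(ms.get("A").units) == 9 and len(ms.get("B").units) == 4


class TestKmeans:
    def test_two_point_masses_recovered(self):
        weights = np.zeros((2, 4, 3))
        weights[:, :2] = 10.0
        weights[:, 2:] = -10.0
        model = model_from_weights(weights)
        ms = kmeans_segmentation(model, 2, seed=0)
        masks = {m.units for m in ms}
        assert masks == {
            frozenset((r, c) for r in range(2) for c in range(2)),
            frozenset((r, c) for r in range(2) for c in range(2, 4)),
        }

    def test_k_equals_units_gives_singletons(self):
        model = grid_model(rows=3, cols=3)
        ms = kmeans_segmentation(model, 9, seed=0)
        assert len(ms) == 9 and all(len(m.units) == 1 for m in ms)

    def test_partition_conserves_genes(self):
        model = grid_model()
        ms = kmeans_segmentation(model, 4, seed=1)
        all_genes = [g for m in ms for g in m.gene_ids]
        assert sorted(all_genes) == sorted(model.gene_ids_)
        all_units = [u for m in ms for u in m.units]
        assert len(all_units) == model.n_units == len(set(all_units))

    def test_wcss_beats_random_partitions(self):
        model = grid_model(seed=3)
        flat = model.weights_.reshape(model.n_units, -1)
        ms = kmeans_segmentation(model, 3, seed=0)

        def wcss(labels):
            tot = 0.0
            for k in set(labels):
                pts = flat[np.asarray(labels) == k]
                tot += ((pts - pts.mean(axis=0)) ** 2).sum()
            return tot

        km_labels = np.zeros(model.n_units, dtype=int)
        for i, m in enumerate(ms):
            for (r, c) in m.units:
                km_labels[r * model.grid_cols + c] = i
        rng = np.random.default_rng(0)
        random_wcss = [
            wcss(rng.integers(0, 3, size=model.n_units)) for _ in range(50)
        ]
        assert wcss(km_labels) <= min(random_wcss)

    def test_k_out_of_range_is_fatal(self):
        model = grid_model(rows=2, cols=2)
        with pytest.raises(DataError):
            kmeans_segmentation(model, 5)


class TestCorrelationCluster:
    def test_identical_weights_make_one_module(self):
        weights = np.tile(np.array([1.0, 2.0, 3.0]), (4, 4, 1))
        model = model_from_weights(weights)
        ms = correlation_cluster_segmentation(model, 0.9)
        assert len(ms) == 1 and len(ms.modules[0].units) == 16

    def test_threshold_above_max_correlation_gives_singletons(self):
        model = grid_model(seed=5)
        ms = correlation_cluster_segmentation(model, 0.9999)
        assert len(ms) == model.n_units

    def test_anticorrelated_halves_split_in_two(self):
        base = np.array([1.0, -1.0, 2.0, -2.0])
        weights = np.empty((4, 4, 4))
        weights[:, :2] = base
        weights[:, 2:] = -base
        model = model_from_weights(weights)
        ms = correlation_cluster_segmentation(model, 0.5)
        masks = {m.units for m in ms}
        assert masks == {
            frozenset((r, c) for r in range(4) for c in range(2)),
            frozenset((r, c) for r in range(4) for c in range(2, 4)),
        }


class TestDmap:
    def test_uniform_weights_one_module(self):
        weights = np.full((5, 5, 3), 1.5)
        model = model_from_weights(weights)
        ms = dmap_segmentation(model, boundary_quantile=0.9)
        assert len(ms) == 1 and len(ms.modules[0].units) == 25

    def test_sharp_jump_splits_halves(self):
        weights = np.zeros((6, 7, 2))
        weights[:, :3] = 0.0
        weights[:, 3] = 50.0  # ridge column
        weights[:, 4:] = 100.0
        model = model_from_weights(weights)
        ms = dmap_segmentation(model, boundary_quantile=0.8)
        masks = sorted((m.units for m in ms), key=len, reverse=True)
        assert len(ms) == 2
        assert frozenset((r, c) for r in range(6) for c in range(3)) in masks
        assert frozenset((r, c) for r in range(6) for c in range(4, 7)) in masks

    def test_distance_map_matches_brute_force_3x3(self):
        model = grid_model(rows=3, cols=3, seed=7)
        dmap = distance_map(model)
        for r in range(3):
            for c in range(3):
                ds = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 3 and 0 <= cc < 3:
                            ds.append(np.linalg.norm(
                                model.weights_[r, c] - model.weights_[rr, cc]))
                assert dmap[r, c] == pytest.approx(np.mean(ds), rel=1e-12)


class TestSpatialScore:
    def test_single_unit_module_equals_metagene_profile(self):
        model = grid_model()
        values = np.zeros((6, 6))
        values[2, 3] = 1.0
        ms = overexpression_modules(model, [portrait_from(values)], min_units=1)
        score = module_spatial_score(model, ms, "A")
        np.testing.assert_allclose(score.to_numpy(), model.weights_[2, 3])

    def test_whole_grid_module_is_mean_of_metagenes(self):
        from spotsom.segmentation import Module, ModuleSet

        model = grid_model()
        units = frozenset((r, c) for r in range(6) for c in range(6))
        ms = ModuleSet([Module("A", units, list(model.gene_ids_), "kmeans")],
                       "kmeans", (6, 6))
        score = module_spatial_score(model, ms, "A")
        np.testing.assert_allclose(
            score.to_numpy(), model.weights_.reshape(36, -1).mean(axis=0)
        )

    def test_unknown_label_is_fatal(self):
        model = grid_model()
        ms = overexpression_modules(model, [portrait_from(np.zeros((6, 6)))])
        with pytest.raises(DataError):
            module_spatial_score(model, ms, "Z")

    def test_planted_module_scores_higher_in_home_domain(
        self, small_dataset, small_model
    ):
        _, _, truth = small_dataset
        labels = truth.as_labels()
        portraits = [
            small_model.group_portrait(labels.barcodes_for(l), label=l)
            for l in labels.unique_labels
        ]
        ms = overexpression_modules(small_model, portraits)
        assert len(ms) >= 1
        found = 0
        for name, genes in truth.module_genes.items():
            planted = set(genes)
            best = max(
                ms.modules,
                key=lambda m: len(planted & set(m.gene_ids)) / len(planted | set(m.gene_ids)),
            )
            score = module_spatial_score(small_model, ms, best.label)
            dom = truth.module_domain[name]
            inside = [score[b] for b in score.index if truth.spot_domain[b] == dom]
            outside = [score[b] for b in score.index if truth.spot_domain[b] != dom]
            found += np.median(inside) > np.median(outside)
        assert found == len(truth.module_genes)
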