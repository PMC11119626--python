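import numpy as np
import pytest
from scipy import ndimage

from spotsom.som import Portrait, SomPortrayal, train_som
from spotsom.types import DataError, ExpressionMatrix

from conftest import model_from_weights


def brute_force_bmu(weights_flat, grid_cols, profile):
    """Independent oracle: exhaustive scan in row-major order, first minimum."""
    best, best_d = None, np.inf
    for i, w in enumerate(weights_flat):
        d = float(np.sqrt(((w - profile) ** 2).sum()))
        if d < best_d:
            best, best_d = i, d
    return best // grid_cols, best % grid_cols


class TestTraining:
    def test_same_seed_is_bit_identical(self, small_centralized):
        a = SomPortrayal(grid_rows=5, grid_cols=5, n_epochs=3, random_state=7).fit(small_centralized)
        b = SomPortrayal(grid_rows=5, grid_cols=5, n_epochs=3, random_state=7).fit(small_centralized)
        np.testing.assert_array_equal(a.weights_, b.weights_)
        assert a.gene_assignment_ == b.gene_assignment_

    def test_different_seed_differs(self, small_centralized):
        a = SomPortrayal(grid_rows=5, grid_cols=5, n_epochs=3, random_state=1,
                         init="random").fit(small_centralized)
        b = SomPortrayal(grid_rows=5, grid_cols=5, n_epochs=3, random_state=2,
                         init="random").fit(small_centralized)
        assert not np.array_equal(a.weights_, b.weights_)

    def test_quantization_error_not_worse_than_init(self, small_model):
        assert small_model.quantization_error_ <= small_model.initial_quantization_error_

    def test_point_masses_claim_distinct_units(self):
        """k well-separated gene clusters end on k distinct best-matching units."""
        rng = np.random.default_rng(0)
        centers = np.array([[10.0] * 8, [-10.0] * 8, [10.0] * 4 + [-10.0] * 4])
        profiles = np.vstack([
            c + rng.normal(0, 0.01, size=(15, 8)) for c in centers
        ])
        model = SomPortrayal(grid_rows=4, grid_cols=4, n_epochs=30, random_state=0)
        model.fit(profiles)
        bmus = model.predict(profiles).reshape(3, 15)
        # every mass concentrated on one unit, and the units are distinct
        units = {tuple(np.unique(row)) for row in bmus}
        assert all(len(u) == 1 for u in units)
        assert len({u[0] for u in units}) == 3

    def test_gene_assignment_is_recheckable(self, small_model, small_centralized):
        flat = small_model.weights_.reshape(small_model.n_units, -1)
        for i in range(0, small_centralized.n_genes, 17):
            g = small_centralized.gene_ids[i]
            assert small_model.gene_assignment_[g] == brute_force_bmu(
                flat, small_model.grid_cols, small_centralized.values[i]
            )

    def test_empty_matrix_is_fatal(self):
        with pytest.raises(DataError):
            SomPortrayal(grid_rows=2, grid_cols=2).fit(np.empty((0, 5)))

    def test_centralized_stage_required(self, small_dataset):
        matrix, _, _ = small_dataset
        with pytest.raises(DataError, match="centralized"):
            SomPortrayal(grid_rows=2, grid_cols=2).fit(matrix)

    def test_anticorrelated_modules_form_disjoint_connected_regions(self):
        """Two opposite gene programs settle in two separated grid territories."""
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            pattern = np.concatenate([np.full(10, 2.0), np.full(10, -2.0)])
            up = pattern + rng.normal(0, 0.15, size=(20, 20))
            down = -pattern + rng.normal(0, 0.15, size=(20, 20))
            model = SomPortrayal(grid_rows=6, grid_cols=6, n_epochs=20,
                                 random_state=seed).fit(np.vstack([up, down]))
            masks = []
            for half in (model.gene_ids_[:20], model.gene_ids_[20:]):
                m = np.zeros((6, 6), dtype=bool)
                for g in half:
                    m[model.gene_assignment_[g]] = True
                masks.append(m)
            disjoint = not (masks[0] & masks[1]).any()
            connected = all(
                ndimage.label(m, structure=np.ones((3, 3)))[1] == 1 for m in masks
            )
            ok += disjoint and connected
        assert ok >= 4  # >= 90% of seeds at scale; allow one failure in five


@pytest.fixture(scope="module")
def model3():
    rng = np.random.default_rng(5)
    return SomPortrayal(grid_rows=3, grid_cols=3, n_epochs=5,
                        random_state=5).fit(rng.normal(size=(30, 6)))


class TestBmu:
    def test_exact_weight_vector_maps_to_its_unit(self, model3):
        assert model3.best_matching_unit(model3.weights_[2, 1]) == (2, 1)

    def test_tie_breaks_row_major(self):
        weights = np.zeros((2, 2, 2))
        weights[0, 1] = [1.0, 0.0]
        weights[1, 0] = [0.0, 1.0]
        weights[0, 0] = [5.0, 5.0]
        weights[1, 1] = [5.0, 5.0]
        model = model_from_weights(weights)
        # equidistant from (0,1) and (1,0): row-major rule picks (0,1)
        assert model.best_matching_unit(np.array([0.5, 0.5])) == (0, 1)

    def test_hundred_random_profiles_match_exhaustive_scan(self, model3):
        rng = np.random.default_rng(17)
        flat = model3.weights_.reshape(9, -1)
        for _ in range(100):
            p = rng.normal(size=6)
            assert model3.best_matching_unit(p) == brute_force_bmu(flat, 3, p)

    def test_dimension_mismatch_is_fatal(self, model3):
        with pytest.raises(DataError, match="dimension"):
            model3.best_matching_unit(np.zeros(4))


class TestPortraits:
    def test_flat_model_gives_flat_portrait(self):
        model = model_from_weights(np.full((3, 3, 4), 2.5))
        p = model.spot_portrait("s1")
        np.testing.assert_array_equal(p.values, np.full((3, 3), 2.5))

    def test_stacked_portraits_reconstruct_weight_tensor(self, small_model):
        stack = np.stack(
            [small_model.spot_portrait(b).values for b in small_model.spot_barcodes_],
            axis=2,
        )
        np.testing.assert_array_equal(stack, small_model.weights_)

    def test_hand_built_2x2_portrait_reads_component(self):
        weights = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        model = model_from_weights(weights)
        p = model.spot_portrait("s2")  # third component of each weight vector
        np.testing.assert_array_equal(p.values, weights[:, :, 2])
        assert p.kind == "single_spot" and p.subject == "s2"

    def test_unknown_barcode_is_fatal(self, small_model):
        with pytest.raises(DataError, match="unknown"):
            small_model.spot_portrait("nope")

    def test_group_of_one_equals_single_portrait(self, small_model):
        b = small_model.spot_barcodes_[4]
        np.testing.assert_array_equal(
            small_model.group_portrait([b]).values, small_model.spot_portrait(b).values
        )

    def test_opposite_portraits_average_to_zero(self):
        weights = np.zeros((2, 2, 2))
        weights[:, :, 0] = [[1, -2], [3, 4]]
        weights[:, :, 1] = -weights[:, :, 0]
        model = model_from_weights(weights)
        p = model.group_portrait(["s0", "s1"])
        np.testing.assert_allclose(p.values, 0.0)
        assert p.kind == "group_mean"

    def test_group_mean_matches_tensor_mean(self, small_model):
        rng = np.random.default_rng(2)
        members = list(rng.choice(small_model.spot_barcodes_, 5, replace=False))
        idx = [small_model.spot_barcodes_.index(b) for b in members]
        expected = small_model.weights_[:, :, idx].mean(axis=2)
        np.testing.assert_allclose(
            small_model.group_portrait(members).values, expected
        )

    def test_empty_group_is_fatal(self, small_model):
        with pytest.raises(DataError, match="empty"):
            small_model.group_portrait([])


class TestQuantizationError:
    def test_zero_when_genes_sit_on_units(self):
        weights = np.random.default_rng(0).normal(size=(2, 3, 4))
        model = model_from_weights(weights)
        profiles = weights.reshape(6, 4)
        assert model.quantization_error(profiles) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_gene_order(self, small_model, small_centralized):
        rng = np.random.default_rng(3)
        perm = rng.permutation(small_centralized.n_genes)
        a = small_model.quantization_error(small_centralized.values)
        b = small_model.quantization_error(small_centralized.values[perm])
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_brute_force_mean_of_minima(self, small_model):
        rng = np.random.default_rng(9)
        profiles = rng.normal(size=(20, small_model.n_features_in_))
        flat = small_model.weights_.reshape(small_model.n_units, -1)
        expected = np.mean([
            min(np.linalg.norm(w - p) for w in flat) for p in profiles
        ])
        assert small_model.quantization_error(profiles) == pytest.approx(expected, rel=1e-9)


def test_train_som_facade(small_centralized):
    model = train_som(small_centralized, grid_rows=4, grid_cols=4, n_epochs=2,
                      random_state=0)
    assert model.weights_.shape == (4, 4, small_centralized.n_spots)


def test_portrait_rejects_non_finite():
    with pytest.raises(DataError):
        Portrait(np.array([[np.nan, 0.0]]), subject="x")
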