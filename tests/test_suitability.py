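"""Normalization, range distance, surface scoring, classification, masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecorange import (ClassificationScheme, GridLayer, GridTransform,
                      LayerStack, classify_surface, extract_values,
                      final_mask, fit_envelope, fit_normalization,
                      generate_landscape, normalize_value, range_distance,
                      run_scoring, sample_occurrences, score_cell,
                      score_surface, soil_suitability)
from ecorange.envelope import FactorEnvelope
from ecorange.suitability import (DegenerateLayerError, NormalizationParams,
                                  normalize_envelope)
from conftest import brute_force_distance_surface, small_config


def _params(lo=0.0, hi=50.0):
    return NormalizationParams(bounds={"f": (lo, hi)})


class TestNormalization:
    def test_anchors(self):
        p = _params(0.0, 50.0)
        assert normalize_value(50.0, "f", p) == 100.0
        assert normalize_value(0.0, "f", p) == 0.0
        assert normalize_value(25.0, "f", p) == 50.0

    def test_no_clamping_outside_layer_range(self):
        p = _params(0.0, 50.0)
        assert normalize_value(60.0, "f", p) == 120.0
        assert normalize_value(-5.0, "f", p) == -10.0

    def test_fit_uses_valid_cells_only(self, tiny_layer):
        soil = tiny_layer.with_values(np.zeros((4, 4)), name="soil", nodata=-1)
        stack = LayerStack(layers={"temp": tiny_layer}, soil=soil)
        params = fit_normalization(stack)
        assert params.bounds["temp"] == (0.0, 15.0)  # the -9999 cell excluded

    def test_constant_layer_rejected(self, tiny_layer):
        const = tiny_layer.with_values(np.full((4, 4), 7.0), name="flat")
        soil = tiny_layer.with_values(np.zeros((4, 4)), name="soil", nodata=-1)
        stack = LayerStack(layers={"flat": const}, soil=soil)
        with pytest.raises(DegenerateLayerError, match="flat"):
            fit_normalization(stack)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=24, unique=True))
    def test_anchor_property_arbitrary_layers(self, values):
        """Layer max maps to exactly 100 and min to exactly 0, always."""
        arr = np.array(values, dtype=float)
        p = NormalizationParams(bounds={"f": (float(arr.min()), float(arr.max()))})
        out = normalize_value(arr, "f", p)
        assert out[arr.argmax()] == 100.0
        assert out[arr.argmin()] == 0.0


class TestRangeDistance:
    @pytest.mark.parametrize("v, lo, hi, expected", [
        (37.5, 20.0, 60.0, 0.0),   # strictly inside
        (20.0, 20.0, 60.0, 0.0),   # closed at the lower bound
        (60.0, 20.0, 60.0, 0.0),   # closed at the upper bound
        (65.0, 20.0, 60.0, 5.0),   # above: distance to hi
        (12.0, 20.0, 60.0, 8.0),   # below: distance to lo
        (5.0, 7.0, 7.0, 2.0),      # degenerate range
    ])
    def test_cases(self, v, lo, hi, expected):
        assert range_distance(v, lo, hi) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-500, 500), st.floats(-200, 200), st.floats(0, 300))
    def test_zero_iff_inside(self, v, lo, width):
        hi = lo + width
        d = range_distance(v, lo, hi)
        if lo <= v <= hi:
            assert d == 0.0
        else:
            assert d == pytest.approx(min(abs(v - lo), abs(v - hi)))
            assert d > 0.0

    def test_continuity_at_bounds(self):
        eps = 1e-9
        assert range_distance(20.0 - eps, 20.0, 60.0) <= eps * 1.01
        assert range_distance(60.0 + eps, 20.0, 60.0) <= eps * 1.01


class TestScoreCell:
    def test_all_inside_is_zero(self):
        assert score_cell([1.0, 2.0], [(0.0, 5.0), (0.0, 5.0)]) == 0.0

    def test_pythagorean_aggregate(self):
        # two factors outside by 3 and 4 -> Euclidean 5
        assert score_cell([8.0, 9.0], [(0.0, 5.0), (0.0, 5.0)]) == 5.0

    def test_single_factor_reduction(self):
        d = score_cell([7.0, 1.0, 1.0], [(0.0, 5.0), (0.0, 5.0), (0.0, 5.0)])
        assert d == range_distance(7.0, 0.0, 5.0) == 2.0


@pytest.mark.parametrize("shape", [(20, 20), (33, 47), (50, 50)])
def test_score_surface_matches_brute_force(shape):
    """Vectorized surface equals the scalar cell-by-cell oracle bit-for-bit."""
    cfg = small_config(seed=shape[0], n_rows=shape[0], n_cols=shape[1])
    land = generate_landscape(cfg)
    occ = sample_occurrences(land, 100, seed=1)
    env = fit_envelope(extract_values(land.stack, occ))
    surface = score_surface(land.stack, env)
    oracle = brute_force_distance_surface(land.stack, env)
    np.testing.assert_array_equal(surface.values, oracle)


def test_score_surface_with_nodata_propagation(tiny_layer):
    soil = tiny_layer.with_values(np.zeros((4, 4)), name="soil", nodata=-1)
    stack = LayerStack(layers={"temp": tiny_layer}, soil=soil)
    env = FactorEnvelope(species="s", ranges={"temp": (2.0, 9.0)},
                         soil_classes=frozenset({0}), n_points_used=3)
    surface = score_surface(stack, env)
    assert surface.values[1, 2] == surface.nodata  # nodata input cell
    assert (surface.values[surface.valid] >= 0).all()


def test_training_cells_score_zero(landscape):
    """Cells holding the occurrences that fit the envelope are at distance 0."""
    occ = sample_occurrences(landscape, 200, seed=17)
    sample = extract_values(landscape.stack, occ)
    env = fit_envelope(sample)
    surface = score_surface(landscape.stack, env)
    rows = sample.valid_rows()
    r, c = landscape.stack.transform.cell_of(rows["longitude"].to_numpy(),
                                             rows["latitude"].to_numpy())
    assert (surface.values[r, c] == 0.0).all()


def test_scale_equivariance(landscape):
    """Rescaling one factor's layer and envelope leaves the surface unchanged."""
    occ = sample_occurrences(landscape, 120, seed=23)
    env = fit_envelope(extract_values(landscape.stack, occ))
    base = score_surface(landscape.stack, env)

    k = 3.7
    scaled_layer = landscape.stack.layers["temp"]
    scaled_layer = scaled_layer.with_values(scaled_layer.values * k)
    stack2 = LayerStack(layers={**landscape.stack.layers, "temp": scaled_layer},
                        soil=landscape.stack.soil,
                        factor_order=landscape.stack.factor_order)
    lo, hi = env.ranges["temp"]
    env2 = FactorEnvelope(species=env.species,
                          ranges={**env.ranges, "temp": (lo * k, hi * k)},
                          soil_classes=env.soil_classes,
                          n_points_used=env.n_points_used)
    scaled = score_surface(stack2, env2)
    np.testing.assert_allclose(scaled.values, base.values, rtol=1e-10, atol=1e-10)


class TestClassification:
    def _distance(self, values):
        t = GridTransform(west=0.0, north=float(len(values)), dx=1.0, dy=1.0)
        return GridLayer("distance", "normalized", np.asarray(values, dtype=float),
                         t, nodata=-1.0)

    def test_zero_is_class_zero(self):
        scheme = ClassificationScheme.equal_width(8.0, n_bins=4)
        cls = classify_surface(self._distance([[0.0, 1.0], [5.0, 8.0]]), scheme)
        assert cls.values[0, 0] == 0

    def test_boundary_goes_to_lower_class(self):
        scheme = ClassificationScheme(thresholds=(2.0, 4.0), labels=("a", "b", "c"))
        cls = classify_surface(self._distance([[2.0, 2.0001], [4.0, 5.0]]), scheme)
        assert cls.values[0, 0] == 1
        assert cls.values[0, 1] == 2
        assert cls.values[1, 0] == 2
        assert cls.values[1, 1] == 2

    def test_all_zero_surface_single_class(self):
        scheme = ClassificationScheme.equal_width(0.0)
        cls = classify_surface(self._distance([[0.0, 0.0]]), scheme)
        assert set(np.unique(cls.values)) == {0}

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ClassificationScheme(thresholds=(3.0, 2.0), labels=("a", "b", "c"))
        with pytest.raises(ValueError):
            ClassificationScheme(thresholds=(0.0,), labels=("a", "b"))


class TestMasks:
    def _soil(self):
        t = GridTransform(west=0.0, north=2.0, dx=1.0, dy=1.0)
        return GridLayer("soil", "category", np.array([[1, 2], [3, -1]]), t, nodata=-1)

    def test_soil_membership(self):
        m = soil_suitability(self._soil(), {1, 3})
        assert m.values[0, 0] == 1 and m.values[0, 1] == 0 and m.values[1, 0] == 1
        assert m.values[1, 1] == m.nodata  # nodata propagates

    def test_all_codes_suitable(self):
        m = soil_suitability(self._soil(), {1, 2, 3})
        assert (m.values[m.valid] == 1).all()

    def test_final_mask_intersection(self):
        t = GridTransform(west=0.0, north=2.0, dx=1.0, dy=1.0)
        classes = GridLayer("c", "class", np.array([[0, 0], [1, 0]]), t, nodata=-1)
        soil = GridLayer("m", "bool", np.array([[1, 0], [1, 1]]), t, nodata=255)
        fm = final_mask(classes, soil)
        np.testing.assert_array_equal(fm.values, [[1, 0], [0, 1]])
        # empty suitable set -> all false
        fm0 = final_mask(classes, soil, suitable_classes=())
        assert (fm0.values[fm0.valid] == 0).all()


def test_zero_set_characterization(landscape):
    """final mask true ⟺ inside the envelope on all factors AND suitable soil."""
    occ = sample_occurrences(landscape, 250, seed=31)
    env = fit_envelope(extract_values(landscape.stack, occ))
    result = run_scoring(landscape.stack, env)
    got = result.final_bool()
    from conftest import brute_force_truth
    expected = brute_force_truth(landscape.stack, env.ranges, env.soil_classes)
    np.testing.assert_array_equal(got, expected)


def test_monotonicity_randomized(landscape):
    """Widening any range or adding soil classes never loses a suitable cell."""
    rng = np.random.default_rng(77)
    occ = sample_occurrences(landscape, 150, seed=41)
    env = fit_envelope(extract_values(landscape.stack, occ))
    base = run_scoring(landscape.stack, env).final_bool()
    all_soils = set(range(landscape.config.n_soil_classes))
    for _ in range(25):
        name = rng.choice(list(env.ranges))
        lo, hi = env.ranges[name]
        pad_lo, pad_hi = rng.uniform(0, 5, size=2)
        wider = {**env.ranges, name: (lo - pad_lo, hi + pad_hi)}
        extra = set(rng.choice(sorted(all_soils), size=rng.integers(0, 3), replace=False))
        env2 = FactorEnvelope(species=env.species, ranges=wider,
                              soil_classes=frozenset(env.soil_classes | extra),
                              n_points_used=env.n_points_used)
        wider_mask = run_scoring(landscape.stack, env2).final_bool()
        assert not (base & ~wider_mask).any()
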