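import numpy as np
import pytest

from plrkit import heatmap_model as hm
from plrkit.errors import ValidationError
from plrkit.heatmap_model import ContributionMap, PupilMatrix
from plrkit.kinetics import DecayRateCurve


IG = np.arange(-2.0, 3.1, 1.0)  # log10 lux
TG_T = np.arange(0.0, 31.0, 1.0)
TG_S = np.arange(30.0, 600.0, 30.0)


def flat_curve(value):
    return lambda lux: value


def matrix_from(values, phase="transient", genotype="x"):
    values = np.asarray(values, dtype=float)
    ig = np.arange(values.shape[0], dtype=float)
    tg = np.arange(values.shape[1], dtype=float)
    return PupilMatrix(genotype, phase, ig, tg, values)


def map_from(values, component="rod", kind="necessity"):
    values = np.asarray(values, dtype=float)
    ig = np.arange(values.shape[0], dtype=float)
    tg = np.arange(values.shape[1], dtype=float)
    return ContributionMap(component, kind, "transient", ig, tg, values)


class TestTransientMatrix:
    def test_time_zero_column_fully_open(self, wt_spec):
        mat = hm.build_transient_matrix(
            wt_spec.transient_curve(), 0.63, time_grid=TG_T, intensity_grid=IG
        )
        assert np.allclose(mat.values[:, 0], 1.0)

    def test_long_time_asymptote_is_plateau(self, wt_spec):
        curve = wt_spec.transient_curve()
        mat = hm.build_transient_matrix(
            curve, 0.63, time_grid=np.array([0.0, 100.0]), intensity_grid=IG
        )
        assert np.allclose(mat.values[:, 1], curve(10.0**IG), atol=1e-6)

    def test_half_life_midpoint_closed_form(self):
        mat = hm.build_transient_matrix(
            flat_curve(0.2), 0.6301, time_grid=np.array([0.0, 1.1]),
            intensity_grid=IG,
        )
        assert np.allclose(mat.values[:, 1], 0.6, atol=1e-4)

    def test_cells_in_unit_interval(self, wt_spec):
        mat = hm.build_transient_matrix(
            wt_spec.transient_curve(), 0.63, time_grid=TG_T, intensity_grid=IG
        )
        assert np.all(mat.values > 0) and np.all(mat.values <= 1)


class TestSustainedMatrix:
    def _curves(self, p_trans, p_sust, rate_per_min):
        k = DecayRateCurve(rate_per_min, rate_per_min, 1.0, 1.0)
        return flat_curve(p_trans), flat_curve(p_sust), k

    def test_equal_plateaus_give_constant_rows(self):
        ct, cs, k = self._curves(0.3, 0.3, 0.2)
        mat = hm.build_sustained_matrix(ct, cs, k, time_grid=TG_S, intensity_grid=IG)
        assert np.allclose(mat.values, 0.3)

    def test_boundary_column_equals_transient_plateau(self, wt_spec):
        curve_t = wt_spec.transient_curve()
        curve_s = wt_spec.sustained_curve()
        k = wt_spec.sustained.decay_rate_curve()
        mat = hm.build_sustained_matrix(
            curve_t, curve_s, k, time_grid=TG_S, intensity_grid=IG
        )
        assert np.array_equal(mat.values[:, 0], np.asarray(curve_t(10.0**IG)))

    def test_half_life_midpoint_closed_form(self):
        # from 0.2 toward 0.9 with a 4-min half-life: halfway after 4 min
        ct, cs, k = self._curves(0.2, 0.9, np.log(2) / 4.0)
        tg = np.array([30.0, 30.0 + 240.0])
        mat = hm.build_sustained_matrix(ct, cs, k, time_grid=tg, intensity_grid=IG)
        assert np.allclose(mat.values[:, 1], 0.55, atol=1e-12)


class TestAverageAndMaps:
    def test_average_of_identical_is_identity(self):
        m = matrix_from([[1.0, 0.5], [0.4, 0.2]])
        avg = hm.average_matrices([m, m])
        assert np.array_equal(avg.values, m.values)

    def test_average_hand_mean_and_order_invariance(self):
        a = matrix_from([[1.0, 0.5], [0.4, 0.2]])
        b = matrix_from([[0.8, 0.3], [0.2, 0.2]])
        avg1 = hm.average_matrices([a, b])
        avg2 = hm.average_matrices([b, a])
        assert np.allclose(avg1.values, [[0.9, 0.4], [0.3, 0.2]])
        assert np.array_equal(avg1.values, avg2.values)

    def test_necessity_cases(self):
        wt = matrix_from([[0.2, 0.2], [0.7, 0.9]])
        assert np.allclose(hm.necessity_map(wt, wt, "rod").values, 0.0)
        ko_blind = matrix_from(np.ones((2, 2)))
        n = hm.necessity_map(wt, ko_blind, "rod")
        assert np.allclose(n.values, 1.0 - wt.values)
        ko = matrix_from([[0.7, 0.2], [0.7, 0.9]])
        assert hm.necessity_map(wt, ko, "rod").values[0, 0] == pytest.approx(0.5)

    def test_necessity_clamps_negative_differences(self):
        wt = matrix_from([[0.5, 0.5]])
        ko_better = matrix_from([[0.3, 0.5]])  # KO constricts more than WT
        n = hm.necessity_map(wt, ko_better, "rod")
        assert np.all(n.values >= 0)

    def test_necessity_monotone_in_knockout_deficit(self):
        rng = np.random.default_rng(0)
        wt = matrix_from(rng.uniform(0.1, 0.9, (4, 5)))
        ko = matrix_from(rng.uniform(0.1, 0.9, (4, 5)))
        worse = matrix_from(np.clip(ko.values + 0.05, None, 1.0))
        n1 = hm.necessity_map(wt, ko, "rod").values
        n2 = hm.necessity_map(wt, worse, "rod").values
        assert np.all(n2 >= n1)

    def test_sufficiency_cases(self):
        blind = matrix_from(np.ones((2, 2)))
        assert np.allclose(hm.sufficiency_map(blind, "rod").values, 0.0)
        only = matrix_from([[0.35, 0.35]])
        assert np.allclose(hm.sufficiency_map(only, "rod").values, 0.65)

    def test_contribution_is_cellwise_max_oracle(self):
        rng = np.random.default_rng(1)
        n = map_from(rng.uniform(0, 1, (6, 7)), kind="necessity")
        s = map_from(rng.uniform(0, 1, (6, 7)), kind="sufficiency")
        c = hm.contribution_map(n, s)
        expected = np.array(
            [
                [max(n.values[i, j], s.values[i, j]) for j in range(7)]
                for i in range(6)
            ]
        )
        assert np.array_equal(c.values, expected)
        assert np.all(c.values >= n.values) and np.all(c.values >= s.values)

    def test_contribution_without_sufficiency_equals_necessity(self):
        n = map_from([[0.3, 0.1]], component="glutamate", kind="necessity")
        c = hm.contribution_map(n)
        assert c.kind == "contribution"
        assert np.array_equal(c.values, n.values)

    def test_component_mismatch_rejected(self):
        n = map_from([[0.3]], component="rod", kind="necessity")
        s = map_from([[0.5]], component="cone", kind="sufficiency")
        with pytest.raises(ValidationError):
            hm.contribution_map(n, s)

    def test_grid_mismatch_rejected(self):
        a = matrix_from([[0.5, 0.5]])
        b = matrix_from([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError):
            hm.necessity_map(a, b, "rod")
        with pytest.raises(ValidationError):
            hm.average_matrices([a, b])


class TestConeDecayAdjustment:
    def test_zero_rate_leaves_matrix_unchanged(self):
        m = matrix_from([[1.0, 0.5, 0.4, 0.6, 0.8]])
        adj = hm.apply_cone_decay_adjustment(m, 0.0)
        assert np.array_equal(adj.values, m.values)

    def test_half_life_past_minimum_halves_depth(self):
        rate = np.log(2)  # half-life 1 s on a 1-s time grid
        m = matrix_from([[1.0, 0.4, 0.4, 0.4]])  # minimum at t=1
        adj = hm.apply_cone_decay_adjustment(m, rate)
        # one half-life past the minimum the 0.6 depth has halved
        assert adj.values[0, 2] == pytest.approx(1.0 - 0.3)
        assert adj.values[0, 3] == pytest.approx(1.0 - 0.15)

    def test_never_deeper_than_unadjusted(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.uniform(0.2, 1.0, (5, 8)))
        adj = hm.apply_cone_decay_adjustment(m, 0.3)
        assert np.all(adj.values >= m.values - 1e-15)
        assert np.all(adj.values >= m.values.min(axis=1, keepdims=True))


class TestComposeRGB:
    def test_all_zero_maps_give_black_image(self):
        z = map_from(np.zeros((3, 4)))
        img = hm.compose_rgb(red=z)
        assert img.shape == (3, 4, 3)
        assert np.all(img == 0)

    def test_full_rod_contribution_is_pure_red(self):
        r = map_from(np.ones((2, 2)), component="rod")
        img = hm.compose_rgb(red=r)
        assert np.all(img[:, :, 0] == 255)
        assert np.all(img[:, :, 1:] == 0)

    def test_channel_rounding(self):
        r = map_from(np.full((1, 1), 0.5), component="rod")
        b = map_from(np.full((1, 1), 0.5), component="melanopsin")
        img = hm.compose_rgb(red=r, blue=b)
        assert tuple(img[0, 0]) == (128, 0, 128)

    def test_duplicate_map_assignment_rejected(self):
        r = map_from(np.ones((1, 1)))
        with pytest.raises(ValidationError):
            hm.compose_rgb(red=r, green=r)

    def test_png_round_trip(self, tmp_path):
        from PIL import Image

        r = map_from(np.linspace(0, 1, 12).reshape(3, 4), component="rod")
        img = hm.compose_rgb(red=r)
        path = tmp_path / "map.png"
        hm.save_rgb_png(img, path)
        loaded = np.asarray(Image.open(path))
        assert np.array_equal(loaded, img[::-1])
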