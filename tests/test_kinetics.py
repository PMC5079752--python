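import numpy as np
import pytest

from plrkit import kinetics
from plrkit.errors import DegenerateFitError, ValidationError


def one_phase(t, y0, plateau, k, t_offset=0.0):
    tau = np.clip(np.asarray(t, float) - t_offset, 0.0, None)
    return plateau + (y0 - plateau) * np.exp(-k * tau)


class TestOnePhase:
    @pytest.mark.parametrize(
        "y0, plateau, k, offset",
        [(1.0, 0.2, 0.63, 0.0), (1.0, 0.5, 0.1444, 0.0), (1.0, 0.3, 0.5, 3.0)],
    )
    def test_noiseless_recovery(self, y0, plateau, k, offset):
        t = np.arange(0.0, 30.0, 0.25)
        fit = kinetics.fit_one_phase((t, one_phase(t, y0, plateau, k, offset)),
                                     t_offset=offset)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.plateau == pytest.approx(plateau, abs=1e-6)
        assert fit.y0 == pytest.approx(y0, abs=1e-6)

    def test_constant_trace_is_degenerate(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(DegenerateFitError):
            kinetics.fit_one_phase((t, np.ones_like(t)))

    def test_invariant_to_pre_offset_samples_at_y0(self):
        offset = 3.0
        t = np.arange(offset, 30.0, 0.5)
        y = one_phase(t, 1.0, 0.25, 0.4, offset)
        fit1 = kinetics.fit_one_phase((t, y), t_offset=offset)
        t2 = np.concatenate([[0.0, 1.0, 2.0], t])
        y2 = np.concatenate([[1.0, 1.0, 1.0], y])
        fit2 = kinetics.fit_one_phase((t2, y2), t_offset=offset)
        assert fit2.k == pytest.approx(fit1.k, rel=1e-9)
        assert fit2.plateau == pytest.approx(fit1.plateau, abs=1e-9)

    def test_noisy_half_life_recovery_sanity(self):
        # smaller-scale version of the 200-trace recovery check
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 30.0, 1.0)
        errors = []
        for _ in range(20):
            y = one_phase(t, 1.0, 0.2, 0.63) + rng.normal(0, 0.03, t.size)
            fit = kinetics.fit_one_phase((t, y))
            errors.append(abs(fit.half_life - np.log(2) / 0.63) / (np.log(2) / 0.63))
        assert np.median(errors) < 0.10


class TestTwoPhase:
    def test_pure_one_phase_data_reduces(self):
        t = np.arange(0.0, 30.0, 0.5)
        fit = kinetics.fit_two_phase((t, one_phase(t, 1.0, 0.2, 0.8)))
        assert fit.kind == "one_phase"
        assert fit.reduced_to_one_phase

    def test_noiseless_biexponential_round_trip(self):
        t = np.arange(0.0, 30.0, 0.5)
        y = 0.6 - 0.5 * np.exp(-1.0 * t) + 0.3 * np.exp(-0.2 * t)
        fit = kinetics.fit_two_phase((t, y))
        assert fit.kind == "two_phase"
        assert fit.plateau == pytest.approx(0.6, abs=1e-4)
        # faster phase reported first
        assert fit.k == pytest.approx(1.0, rel=1e-4)
        assert fit.span1 == pytest.approx(-0.5, abs=1e-4)
        assert fit.k2 == pytest.approx(0.2, rel=1e-4)
        assert fit.span2 == pytest.approx(0.3, abs=1e-4)

    def test_constrict_then_redilate_minimum_before_30s(self, library):
        from plrkit import pupil_io, synthetic_data as sd

        trace = sd.generate_trace(
            library["cone_only"], 1000.0, 30.0, 0.25, seed=0, noise_sd=0.0
        )
        rel = pupil_io.relative_trace(trace)
        fit = kinetics.fit_two_phase(rel)
        dense_t = np.linspace(0, 30, 3001)
        t_min = dense_t[np.argmin(fit.predict(dense_t))]
        assert t_min < 30.0


class TestHalfLife:
    @pytest.mark.parametrize(
        "k, expected",
        [(np.log(2), 1.0), (0.6301, 1.1000915), (0.1733, 4.0000577)],
    )
    def test_closed_form(self, k, expected):
        assert kinetics.half_life(k) == pytest.approx(expected, rel=1e-4)

    def test_product_identity(self):
        for k in (0.01, 0.5, 3.0):
            assert kinetics.half_life(k) * k == pytest.approx(np.log(2), rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            kinetics.half_life(0.0)


class TestDecayRateCurve:
    def test_equal_rates_give_constant_curve(self):
        c = kinetics.fit_decay_rate_vs_intensity({1: 0.3, 10: 0.3, 100: 0.3})
        lux = np.array([0.001, 1.0, 5.0, 50.0, 100.0, 1e5])
        assert np.allclose(c(lux), 0.3)

    def test_plateau_clamping_outside_fitted_range(self):
        c = kinetics.fit_decay_rate_vs_intensity({1: 0.35, 10: 0.25, 100: 0.14})
        assert c(0.001) == pytest.approx(0.35)
        assert c(1e5) == pytest.approx(0.14)

    def test_interior_value_matches_grid_search_oracle(self):
        rates = {1: 0.35, 10: 0.25, 100: 0.14}
        c = kinetics.fit_decay_rate_vs_intensity(rates)

        # zooming grid search over (midpoint, slope) minimizing the 10-lux miss
        def value_at_10(mid, slope):
            return 0.14 + (0.35 - 0.14) / (1.0 + 10.0 ** ((1.0 - mid) * slope))

        m_range, s_range = (-1.0, 3.0), (0.01, 10.0)
        for _ in range(8):
            ms = np.linspace(*m_range, 21)
            ss = np.linspace(*s_range, 21)
            M, S = np.meshgrid(ms, ss, indexing="ij")
            err = np.abs(value_at_10(M, S) - 0.25)
            i, j = np.unravel_index(np.argmin(err), err.shape)
            dm = (m_range[1] - m_range[0]) / 20
            ds = (s_range[1] - s_range[0]) / 20
            m_range = (ms[i] - dm, ms[i] + dm)
            s_range = (max(ss[j] - ds, 1e-3), ss[j] + ds)
        oracle_k10 = value_at_10(ms[i], ss[j])
        assert c(10.0) == pytest.approx(oracle_k10, abs=1e-3)
        assert c(10.0) == pytest.approx(0.25, abs=1e-3)

    def test_output_always_within_rate_interval(self):
        c = kinetics.fit_decay_rate_vs_intensity({1: 0.35, 10: 0.30, 100: 0.14})
        lux = 10.0 ** np.linspace(-3, 5, 400)
        out = c(lux)
        assert np.all(out >= 0.14 - 1e-12) and np.all(out <= 0.35 + 1e-12)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValidationError):
            kinetics.fit_decay_rate_vs_intensity({1: 0.3, 10: -0.1, 100: 0.2})
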