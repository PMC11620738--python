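import math

import numpy as np
import pytest

from polascore import (
    AbsoluteClass,
    CalibrationModel,
    GenotypeProfile,
    SignedClass,
    fit_depth_regression,
    plot_violin,
    score_measurement,
    score_measurements,
    simulate_control,
    simulate_reporter,
    summarize,
    t_critical,
)
from polascore.polarity_classification import calls_to_frame

from .conftest import make_measurement


def with_log_ratio(y: float, z: float = 0.0, **kwargs):
    """Measurement whose log10 intensity ratio is exactly representable as y."""
    return make_measurement(proximal=100.0 * 10.0**y, distal=100.0, z=z, **kwargs)


class TestScoreMeasurement:
    def test_normal_call_hand_values(self, reference_model):
        # v_upper = t(95) * 0.0613 ~= 0.1217
        assert reference_model.v_upper == pytest.approx(0.1217, abs=2e-4)
        call = score_measurement(reference_model, with_log_ratio(0.2, z=2.0))
        assert call.y_hat == pytest.approx(-0.0532, abs=1e-12)
        assert call.residual == pytest.approx(0.2532, abs=1e-9)
        assert call.signed_class is SignedClass.normal
        assert call.absolute_class is AbsoluteClass.polarized

    def test_zero_residual_symmetric(self, reference_model):
        m = with_log_ratio(0.0148, z=0.0)
        call = score_measurement(reference_model, m)
        assert call.residual == pytest.approx(0.0, abs=1e-9)
        assert call.signed_class is SignedClass.symmetric
        assert call.absolute_class is AbsoluteClass.unpolarized

    def test_reversed_call(self, reference_model):
        call = score_measurement(reference_model, with_log_ratio(-0.15, z=0.0))
        assert call.residual == pytest.approx(-0.1648, abs=1e-9)
        assert call.signed_class is SignedClass.reversed
        assert call.absolute_class is AbsoluteClass.polarized

    def test_boundary_tie_is_symmetric(self):
        # slope 1, intercept 0: y_hat = z exactly, so residual = -z for y = 0
        t = t_critical(8, 0.05)
        model = CalibrationModel(
            slope=1.0,
            intercept=0.0,
            residual_se=0.05,
            n=10,
            df=8,
            t_crit=t,
            v_upper=t * 0.05,
            v_lower=-t * 0.05,
        )
        m = make_measurement(100.0, 100.0, z=-model.v_upper)
        call = score_measurement(model, m)
        assert call.residual == model.v_upper  # exact float equality
        assert call.signed_class is SignedClass.symmetric
        assert call.absolute_class is AbsoluteClass.unpolarized

    def test_monotone_in_proximal_intensity(self, reference_model):
        order = {SignedClass.reversed: 0, SignedClass.symmetric: 1, SignedClass.normal: 2}
        last = -1
        for proximal in np.geomspace(10, 1000, 60):
            call = score_measurement(
                reference_model, make_measurement(proximal, 100.0, z=0.5)
            )
            rank = order[call.signed_class]
            assert rank >= last
            last = rank

    def test_agrees_with_brute_force(self, reference_model):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            prox, dist = rng.uniform(1, 500, size=2)
            z = rng.uniform(-4, 4)
            m = make_measurement(prox, dist, z)
            call = score_measurement(reference_model, m)
            # independent recomputation path
            y = math.log10(prox / dist)
            y_hat = reference_model.intercept + reference_model.slope * z
            r = y - y_hat
            if r > reference_model.v_upper:
                expect_signed = SignedClass.normal
            elif r < reference_model.v_lower:
                expect_signed = SignedClass.reversed
            else:
                expect_signed = SignedClass.symmetric
            expect_abs = (
                AbsoluteClass.polarized
                if abs(r) > reference_model.v_upper
                else AbsoluteClass.unpolarized
            )
            assert call.residual == pytest.approx(r, abs=1e-12)
            assert call.signed_class is expect_signed
            assert call.absolute_class is expect_abs


class TestSummarize:
    def test_all_symmetric(self, reference_model):
        ms = [with_log_ratio(0.0148, animal_id=f"a{i}") for i in range(10)]
        calls = score_measurements(reference_model, ms)
        (s,) = summarize(calls)
        assert (s.fraction_normal, s.fraction_reversed, s.fraction_symmetric) == (
            0.0,
            0.0,
            1.0,
        )
        assert s.n_calls == 10

    def test_fractions_sum_to_one_and_counts_conserved(self, reference_model):
        rep, _ = simulate_reporter(
            300,
            GenotypeProfile(p_normal=0.4, p_reversed=0.3, p_symmetric=0.3,
                            effect_size=0.3),
            seed=5,
        )
        calls = score_measurements(reference_model, rep)
        for s in summarize(calls):
            assert s.fraction_normal + s.fraction_reversed + s.fraction_symmetric == (
                pytest.approx(1.0, abs=1e-12)
            )
        assert sum(s.n_calls for s in summarize(calls)) == len(calls)

    def test_half_half_reversal_mixture(self, reference_model):
        # mirrors a fully penetrant 50/50 orientation split
        profile = GenotypeProfile(
            p_normal=0.5, p_reversed=0.5, p_symmetric=0.0, effect_size=0.4
        )
        rep, _ = simulate_reporter(2000, profile, seed=9)
        (s,) = summarize(score_measurements(reference_model, rep))
        assert s.fraction_normal == pytest.approx(0.5, abs=0.05)
        assert s.fraction_reversed == pytest.approx(0.5, abs=0.05)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert summarize([]) == []

    def test_groups_sorted_deterministically(self, reference_model):
        ms = [
            with_log_ratio(0.0, genotype=g, animal_id=f"{g}{i}")
            for g in ("mutB", "mutA")
            for i in range(3)
        ]
        keys = [
            (s.genotype, s.cell, s.temperature_c)
            for s in summarize(score_measurements(reference_model, ms))
        ]
        assert keys == sorted(keys)


class TestCallsFrame:
    def test_columns_extend_input_schema(self, reference_model):
        calls = score_measurements(reference_model, [with_log_ratio(0.2, z=1.0)])
        df = calls_to_frame(calls)
        for col in ("y", "y_hat", "residual", "signed_class", "absolute_class"):
            assert col in df.columns


@pytest.fixture(scope="module")
def calls(reference_model):
    rep, _ = simulate_reporter(
        60, GenotypeProfile(p_normal=1.0, p_symmetric=0.0, effect_size=0.3), seed=2
    )
    return score_measurements(reference_model, rep)


class TestPlotViolin:

    def test_signed_figure_written(self, tmp_path, calls, reference_model):
        out = plot_violin(calls, "signed", reference_model, tmp_path / "v.png")
        assert out.exists() and out.stat().st_size > 0

    def test_absolute_summary_non_negative(self, tmp_path, calls, reference_model):
        import pandas as pd

        plot_violin(
            calls,
            "absolute",
            reference_model,
            tmp_path / "a.png",
            summary_path=tmp_path / "a.csv",
        )
        summary = pd.read_csv(tmp_path / "a.csv")
        assert (summary["median"] >= 0).all()
        assert (summary["mean"] >= 0).all()

    def test_summary_deterministic(self, tmp_path, calls, reference_model):
        for name in ("s1", "s2"):
            plot_violin(
                calls,
                "signed",
                reference_model,
                tmp_path / f"{name}.png",
                summary_path=tmp_path / f"{name}.csv",
            )
        assert (tmp_path / "s1.csv").read_bytes() == (tmp_path / "s2.csv").read_bytes()

    def test_single_point_group_skipped(self, tmp_path, calls, reference_model):
        lone = score_measurements(
            reference_model, [with_log_ratio(0.1, genotype="lonely")]
        )
        with pytest.warns(UserWarning, match="skipping"):
            plot_violin(calls + lone, "signed", reference_model, tmp_path / "v.png")

    def test_bad_mode_rejected(self, calls, reference_model, tmp_path):
        with pytest.raises(ValueError):
            plot_violin(calls, "sideways", reference_model, tmp_path / "x.png")


class TestNullFalseCallRate:
    def test_false_call_rate_near_alpha(self):
        """Null leakage: symmetric pairs scored against an independent calibration."""
        profile = GenotypeProfile()
        model = fit_depth_regression(simulate_control(10_000, profile, seed=21))
        rep, truth = simulate_reporter(20_000, profile, seed=22)
        assert set(truth) == {"symmetric"}
        calls = score_measurements(model, rep)
        frac_norm = np.mean([c.signed_class is SignedClass.normal for c in calls])
        frac_rev = np.mean([c.signed_class is SignedClass.reversed for c in calls])
        assert frac_norm + frac_rev == pytest.approx(0.05, abs=0.007)
        assert frac_norm == pytest.approx(0.025, abs=0.006)
        assert frac_rev == pytest.approx(0.025, abs=0.006)


class TestPowerMonotone:
    def test_power_nondecreasing_in_effect(self, reference_model):
        fractions = []
        for effect in (0.0, 0.05, 0.1, 0.2, 0.4):
            profile = GenotypeProfile(
                p_normal=1.0, p_symmetric=0.0, effect_size=effect
            )
            # common random numbers (same seed) make the comparison exact
            rep, _ = simulate_reporter(2000, profile, seed=33)
            calls = score_measurements(reference_model, rep)
            fractions.append(
                np.mean([c.signed_class is SignedClass.normal for c in calls])
            )
        assert fractions == sorted(fractions)
        assert fractions[-1] >= 0.99
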