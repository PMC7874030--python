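import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergylab import (CYCLE_POINTS, LungeCycle, MUSCLES, coactivation,
                        envelope, normalize_for_synergies,
                        normalize_per_direction, time_normalize_cycle)
from synergylab.muscles import (ANKLE_AGONISTS, ANKLE_ANTAGONISTS,
                                HIP_AGONISTS, HIP_ANTAGONISTS, KNEE_AGONISTS,
                                KNEE_ANTAGONISTS)

RATE = 1000.0


def _coactivation_bruteforce(rows):
    """Direct evaluation of the three antagonist/agonist ratio formulas."""
    def mean(names):
        return sum(rows[n] for n in names) / len(names)

    def ratio(num, den):
        out = np.full(num.shape, np.nan)
        np.divide(num, den, out=out, where=den != 0)
        return out

    return (ratio(mean(HIP_ANTAGONISTS), mean(HIP_AGONISTS)),
            ratio(mean(KNEE_ANTAGONISTS), mean(KNEE_AGONISTS)),
            ratio(rows["TA"], mean(ANKLE_AGONISTS)))


class TestEnvelope:
    def test_sine_envelope_matches_rectified_mean(self):
        """A pure 100 Hz sine of amplitude a has mean rectified value 2a/pi."""
        t = np.arange(0, 4.0, 1 / RATE)
        a = 2.5
        env = envelope(a * np.sin(2 * np.pi * 100 * t), RATE)
        mid = env[500:-500]  # skip filter edge transients
        assert abs(mid.mean() - 2 * a / np.pi) / (2 * a / np.pi) < 0.05

    def test_dc_offset_removed(self):
        env = envelope(np.full(4000, 3.7), RATE)
        assert np.all(env[200:-200] < 1e-6)

    def test_zero_in_zero_out(self):
        assert np.allclose(envelope(np.zeros(2000), RATE), 0.0)

    def test_output_non_negative(self, rng):
        env = envelope(rng.normal(size=5000), RATE)
        assert np.all(env >= 0)

    @pytest.mark.parametrize("c", [0.5, 3.0, 42.0])
    def test_positive_homogeneity(self, rng, c):
        """envelope(c x) == c envelope(x) for c > 0."""
        x = rng.normal(size=3000)
        np.testing.assert_allclose(envelope(c * x, RATE),
                                   c * envelope(x, RATE), rtol=1e-9, atol=1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.zeros(100), rate=90.0)


class TestTimeNormalize:
    def test_identity_grid(self, rng):
        """A cycle already sampled as 50 swing + 150 stance points maps to
        itself."""
        x = rng.uniform(size=300)
        cyc = LungeCycle(40, 90, 239)  # swing 50 samples, stance 150
        np.testing.assert_allclose(time_normalize_cycle(x, cyc), x[40:240])

    def test_linear_ramp_preserved(self):
        x = np.linspace(0, 1, 1000)
        cyc = LungeCycle(100, 400, 900)
        out = time_normalize_cycle(x, cyc)
        fitted = np.polyfit(np.arange(100), out[100:], 1)
        assert abs(out[50] - x[400]) < 1e-12  # touchdown at point 50
        # each phase stays a straight line
        swing_resid = out[:50] - np.linspace(x[100], x[399], 50)
        assert np.max(np.abs(swing_resid)) < 1e-9

    def test_sine_downsampling_matches_analytic(self):
        t = np.arange(2000) / RATE
        x = np.sin(2 * np.pi * 2 * t)
        cyc = LungeCycle(0, 500, 1999)
        out = time_normalize_cycle(x, cyc)
        grid_sw = np.linspace(0, 499, 50) / RATE
        grid_st = np.linspace(500, 1999, 150) / RATE
        expected = np.sin(2 * np.pi * 2 * np.concatenate([grid_sw, grid_st]))
        # linear interpolation error bound: (h^2/8) * max|f''|
        h = (1999 - 500) / 149 / RATE
        bound = h ** 2 / 8 * (2 * np.pi * 2) ** 2 + 1e-12
        assert np.max(np.abs(out - expected)) < bound

    def test_short_phase_rejected(self):
        with pytest.raises(ValueError):
            time_normalize_cycle(np.arange(100.0), LungeCycle(10, 11, 50))

    def test_rate_conversion(self):
        x = np.linspace(0, 1, 250)
        cyc = LungeCycle(100, 400, 900, rate=1000.0)  # indices at 1 kHz
        out = time_normalize_cycle(x, cyc, rate=250.0)
        assert out.shape == (CYCLE_POINTS,)
        assert abs(out[50] - x[100]) < 1e-12


class TestSynergyNormalization:
    def _envelopes(self, rng, n=2000):
        return {m: rng.uniform(0.1, 5.0, size=n) for m in MUSCLES}

    def test_rows_span_unit_interval(self, rng):
        env = self._envelopes(rng)
        cycles = [LungeCycle(50, 300, 900), LungeCycle(1000, 1250, 1900)]
        v = normalize_for_synergies(env, cycles)
        assert v.values.shape == (13, 2 * CYCLE_POINTS)
        assert np.allclose(v.values.min(axis=1), 0.0)
        assert np.allclose(v.values.max(axis=1), 1.0)

    def test_single_cycle_has_200_columns(self, rng):
        v = normalize_for_synergies(self._envelopes(rng),
                                    [LungeCycle(0, 300, 1500)])
        assert v.values.shape[1] == CYCLE_POINTS

    def test_constant_channel_flagged_zero(self, rng, caplog):
        env = self._envelopes(rng)
        env["SO"] = np.full(2000, 2.0)
        with caplog.at_level("WARNING"):
            v = normalize_for_synergies(env, [LungeCycle(0, 300, 1500)])
        assert np.allclose(v.values[MUSCLES.index("SO")], 0.0)
        assert any("SO" in r.message for r in caplog.records)

    def test_dead_channel_named(self, rng):
        env = self._envelopes(rng)
        env["GL"] = np.zeros(2000)
        with pytest.raises(ValueError, match="GL"):
            normalize_for_synergies(env, [LungeCycle(0, 300, 1500)])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_invariants_hold_for_random_inputs(self, seed):
        """Every valid input yields a non-negative matrix with unit row
        range and a 200-multiple column count."""
        r = np.random.default_rng(seed)
        env = {m: r.uniform(0, r.uniform(0.5, 10), size=1200)
               for m in MUSCLES}
        n_cyc = int(r.integers(1, 4))
        cycles = [LungeCycle(i * 400 + 5, i * 400 + 105, i * 400 + 395)
                  for i in range(n_cyc)]
        v = normalize_for_synergies(env, cycles)
        assert np.all(v.values >= 0)
        assert v.values.shape[1] == n_cyc * CYCLE_POINTS
        assert np.allclose(v.values.max(axis=1), 1.0)

    def test_cycle_blocks_recover_individual_cycles(self, rng):
        """Slicing column block k equals time-normalizing cycle k alone
        (up to the shared row scaling)."""
        env = self._envelopes(rng)
        cycles = [LungeCycle(50, 300, 900), LungeCycle(1000, 1250, 1900)]
        v = normalize_for_synergies(env, cycles)
        for k, cyc in enumerate(cycles):
            per_cycle = np.vstack([time_normalize_cycle(env[m], cyc)
                                   for m in MUSCLES])
            whole = np.hstack([np.vstack([time_normalize_cycle(env[m], c)
                                          for m in MUSCLES]) for c in cycles])
            lo = whole.min(axis=1, keepdims=True)
            span = whole.max(axis=1, keepdims=True) - lo
            np.testing.assert_allclose(v.cycle(k), (per_cycle - lo) / span,
                                       rtol=1e-12)


class TestDirectionNormalization:
    def test_single_trial_equals_per_trial_max(self, rng):
        env = {m: rng.uniform(0.1, 4.0, size=1500) for m in MUSCLES}
        cycles = [LungeCycle(0, 300, 1400)]
        out = normalize_per_direction([env], [cycles])[0]
        direct = np.vstack([time_normalize_cycle(env[m], cycles[0])
                            for m in MUSCLES])
        np.testing.assert_allclose(out.values,
                                   direct / direct.max(axis=1, keepdims=True),
                                   rtol=1e-12)

    def test_shared_divisor_keeps_smaller_trial_below_one(self, rng):
        env1 = {m: rng.uniform(0.1, 1.0, size=1500) for m in MUSCLES}
        env2 = {m: env1[m] * 2.0 for m in MUSCLES}
        cycles = [LungeCycle(0, 300, 1400)]
        out1, out2 = normalize_per_direction([env1, env2], [cycles, cycles])
        assert np.all(out1.values.max(axis=1) < 1.0 - 1e-9)
        assert np.allclose(out2.values.max(axis=1), 1.0)

    def test_scale_invariance(self, rng):
        env = {m: rng.uniform(0.1, 4.0, size=1500) for m in MUSCLES}
        scaled = {m: 17.3 * env[m] for m in MUSCLES}
        cycles = [LungeCycle(0, 300, 1400)]
        a = normalize_per_direction([env], [cycles])[0]
        b = normalize_per_direction([scaled], [cycles])[0]
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestCoactivation:
    def test_equal_channels_give_unit_ratios(self):
        rows = np.full((13, 100), 0.7)
        series = coactivation(rows)
        for r in (series.hip, series.knee, series.ankle):
            np.testing.assert_allclose(r, 1.0)

    def test_silent_antagonists_give_zero(self):
        rows = {m: np.full(50, 0.5) for m in MUSCLES}
        for m in HIP_ANTAGONISTS + KNEE_ANTAGONISTS + ANKLE_ANTAGONISTS:
            rows[m] = np.zeros(50)
        series = coactivation(rows)
        np.testing.assert_allclose(series.hip, 0.0)
        np.testing.assert_allclose(series.knee, 0.0)
        np.testing.assert_allclose(series.ankle, 0.0)

    def test_zero_denominator_marked_nan(self):
        rows = {m: np.full(10, 0.5) for m in MUSCLES}
        for m in ANKLE_AGONISTS:
            rows[m] = np.zeros(10)
        series = coactivation(rows)
        assert np.isnan(series.ankle).all()
        assert np.isfinite(series.hip).all()

    def test_matches_bruteforce_formulas(self, rng):
        """Pointwise equality with direct evaluation of the ratio formulas
        on 100 random envelope sets."""
        for _ in range(100):
            rows = {m: rng.uniform(0, 1, size=37) for m in MUSCLES}
            series = coactivation(rows)
            hip, knee, ankle = _coactivation_bruteforce(rows)
            np.testing.assert_allclose(series.hip, hip, atol=1e-9)
            np.testing.assert_allclose(series.knee, knee, atol=1e-9)
            np.testing.assert_allclose(series.ankle, ankle, atol=1e-9)
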