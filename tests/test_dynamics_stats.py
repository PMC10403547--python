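"""Unit tests for growth-exponent fitting, resampling and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from segdyn.dynamics_stats import (
    envelopment_index,
    five_number_summary,
    growth_exponent,
    resample_hourly,
    welch_t_test,
)
from segdyn.synthetic import LatticeState


class TestGrowthExponent:
    def test_exact_power_law(self):
        t = np.geomspace(1, 100, 20)
        fit = growth_exponent((t, 3.0 * t**0.5), window=(t[0], t[-1]))
        assert fit.z == pytest.approx(0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        # Noise-free data: the CI collapses onto the slope itself.
        assert fit.ci95[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.ci95[1] == pytest.approx(0.5, abs=1e-9)

    def test_default_window_drops_early_transient(self):
        t = np.geomspace(1, 100, 20)
        v = 3.0 * t**0.5
        v[:5] = v[5]  # flat start must not bias the slope
        fit = growth_exponent((t, v))
        assert fit.z == pytest.approx(0.5, abs=1e-6)

    def test_plateau_only_series_has_no_growth_regime(self):
        t = np.geomspace(1, 100, 12)
        v = np.full(12, 7.0) + np.linspace(0, 1e-4, 12)
        sem = np.full(12, 0.5)
        with pytest.raises(ValueError, match="plateau|constant"):
            growth_exponent((t, v), sem=sem)

    def test_terminal_plateau_excluded(self):
        t = np.geomspace(1, 1000, 30)
        v = 2.0 * t**1.0
        v[t > 100] = v[t <= 100][-1]  # saturation
        sem = np.full(30, 1e-6)
        fit = growth_exponent((t, v), sem=sem)
        assert fit.z == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            growth_exponent((np.array([0.0, 1, 2, 3, 4]), np.ones(5)))


class TestResampleHourly:
    def test_six_point_blocks_average_exactly(self):
        t = np.arange(12) / 6.0
        v = np.arange(12, dtype=float)
        tb, vb = resample_hourly(t, v)
        np.testing.assert_allclose(vb, [2.5, 8.5])
        np.testing.assert_allclose(tb, [t[:6].mean(), t[6:].mean()])

    def test_trailing_partial_block_dropped(self):
        t = np.arange(8) / 6.0
        _, vb = resample_hourly(t, np.ones(8))
        assert len(vb) == 1

    def test_wrong_cadence_rejected(self):
        t = np.arange(12) / 4.0  # 15-minute data
        with pytest.raises(ValueError, match="spacing"):
            resample_hourly(t, np.ones(12))


class TestWelch:
    def test_hand_computed_anchor(self):
        t, df, _ = welch_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0, abs=1e-9)

    @given(
        a=st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        b=st.lists(st.floats(-100, 100), min_size=3, max_size=20),
    )
    @settings(max_examples=60, deadline=None)
    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_matches_scipy(self, a, b):
        a, b = np.array(a), np.array(b)
        # Skip (near-)degenerate draws where the Welch df underflows.
        if max(a.var(ddof=1), b.var(ddof=1)) < 1e-20:
            return
        t, df, p = welch_t_test(a, b)
        ref = spstats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [1.0, 1.0])


class TestFiveNumber:
    def test_trivial_anchor_exact(self):
        s = five_number_summary([1, 2, 3, 4, 5])
        assert s.five_number == (1.0, 2.0, 3.0, 4.0, 5.0)
        assert s.mean == 3.0
        assert s.n == 5

    def test_single_value(self):
        s = five_number_summary([7.0])
        assert s.five_number == (7.0, 7.0, 7.0, 7.0, 7.0)
        assert np.isnan(s.sem)


class TestEnvelopmentIndex:
    @staticmethod
    def _state(labels):
        J = np.zeros((3, 3))
        return LatticeState(
            labels=np.asarray(labels),
            energy_table=J,
            temperature=1.0,
            sweep_count=0,
            seed=0,
            periodic=False,
        )

    def test_hand_built_shell(self):
        # Type 2 forms a full ring around type 1: only type 2 touches medium.
        lab = np.zeros((6, 6), dtype=np.int8)
        lab[1:5, 1:5] = 2
        lab[2:4, 2:4] = 1
        idx = envelopment_index(self._state(lab))
        assert idx.fractions[2] == pytest.approx(1.0)
        assert idx.fractions.get(1, 0.0) == 0.0

    def test_fractions_sum_to_one(self, rng):
        lab = rng.integers(0, 3, size=(12, 12)).astype(np.int8)
        idx = envelopment_index(self._state(lab))
        assert sum(idx.fractions.values()) == pytest.approx(1.0)

    def test_no_medium_rejected(self):
        lab = np.ones((4, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="medium"):
            envelopment_index(self._state(lab))
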