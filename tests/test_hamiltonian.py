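"""Laws of the EDS reference energy, endstate weights and the AEDS boost."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from aedskit import (
    AccelerationParams,
    OffsetVector,
    ThermoContext,
    aeds_boost,
    boosted_force,
    eds_reference_energy,
    endstate_weights,
    make_t4l_like_toy,
    oracle_free_energies,
)

CTX = ThermoContext(300.0)
RT = CTX.RT


def test_thermal_energy_at_300K():
    assert RT == pytest.approx(2.4943, abs=1e-3)


class TestReferenceEnergy:
    @pytest.mark.parametrize(
        "h, off, expected",
        [
            ([-10.0], [0.0], -10.0),  # single endstate is the reference
            ([-10.0, -10.0], [0.0, 0.0], -10.0 - RT * np.log(2.0)),  # symmetry
            ([-10.0, 0.0], [0.0, -5.0], -10.0 - RT * np.log1p(np.exp(-15.0 / RT))),
        ],
    )
    def test_closed_forms(self, h, off, expected):
        assert eds_reference_energy(h, np.array(off), CTX) == pytest.approx(expected, abs=1e-6)

    def test_rejects_empty_and_nonfinite_frames(self):
        with pytest.raises(ValueError):
            eds_reference_energy(np.empty(0), np.empty(0), CTX)
        with pytest.raises(ValueError):
            eds_reference_energy([np.nan, 0.0], [0.0, 0.0], CTX)
        with pytest.raises(ValueError):
            eds_reference_energy([0.0, 0.0], [0.0], CTX)

    @given(
        arrays(float, st.integers(1, 12), elements=st.floats(-1e4, 1e4)),
        arrays(float, st.integers(1, 12), elements=st.floats(-100, 100)),
    )
    def test_lower_bound_and_translation(self, h, off):
        off = off[: len(h)]
        if len(off) < len(h):
            off = np.pad(off, (0, len(h) - len(off)))
        h_r = eds_reference_energy(h, off, CTX)
        assert h_r <= np.min(h - off) + 1e-9
        shifted = eds_reference_energy(h + 7.25, off, CTX)
        assert shifted == pytest.approx(h_r + 7.25, abs=1e-8)

    @given(st.integers(0, 3), st.floats(0.1, 50.0))
    def test_monotone_in_each_endstate_energy(self, idx, bump):
        h = np.array([-5.0, -2.0, 0.0, 3.0])
        off = np.array([0.0, 1.0, -1.0, 0.5])
        before = eds_reference_energy(h, off, CTX)
        h2 = h.copy()
        h2[idx] += bump
        assert eds_reference_energy(h2, off, CTX) >= before - 1e-12

    def test_batch_evaluation_matches_per_frame(self):
        rng = np.random.default_rng(1)
        h = rng.normal(0, 20, size=(17, 5))
        off = rng.normal(0, 5, size=5)
        batch = eds_reference_energy(h, off, CTX)
        single = [eds_reference_energy(row, off, CTX) for row in h]
        np.testing.assert_allclose(batch, single, rtol=1e-14)


class TestWeights:
    def test_symmetry_and_normalization(self):
        np.testing.assert_allclose(endstate_weights([-10.0, -10.0], np.zeros(2), CTX), [0.5, 0.5])
        np.testing.assert_allclose(endstate_weights([-10.0], np.zeros(1), CTX), [1.0])

    def test_logistic_closed_form(self):
        w = endstate_weights([-10.0, 0.0], np.zeros(2), CTX)
        assert w[0] == pytest.approx(1.0 / (1.0 + np.exp(-10.0 / RT)), abs=1e-5)
        assert w[0] == pytest.approx(0.98217, abs=1e-5)

    @given(
        arrays(float, st.integers(1, 64), elements=st.floats(-5e3, 5e3)),
        st.floats(-50, 50),
    )
    def test_sum_one_and_gauge_invariance(self, h, const):
        off = np.zeros(len(h))
        w = endstate_weights(h, off, CTX)
        assert abs(w.sum() - 1.0) < 1e-12
        w2 = endstate_weights(h, off + const, CTX)
        np.testing.assert_allclose(w, w2, atol=1e-12)
        gaps = np.sort(h - off)
        if len(gaps) == 1 or gaps[1] - gaps[0] > 1e-6:  # unique minimum
            assert np.argmax(w) == np.argmin(h - off)


class TestBoost:
    PARAMS = AccelerationParams(-435.0, 64.54, OffsetVector.zeros(("a",)))

    @pytest.mark.parametrize(
        "h_r, h_star, slope",
        [
            (-500.0, -500.0, 1.0),  # below E_min: untouched
            (64.54, -185.23, 0.0),  # at E_max: plateau level (E_min+E_max)/2
            (0.0, -189.39924730752293, 0.1291988629539177),
            (1000.0, -185.23, 0.0),  # above E_max: constant
        ],
    )
    def test_piecewise_values(self, h_r, h_star, slope):
        hs, sl = aeds_boost(h_r, self.PARAMS)
        assert hs == pytest.approx(h_star, abs=1e-4)
        assert sl == pytest.approx(slope, abs=1e-6)

    def test_requires_valid_band(self):
        with pytest.raises(ValueError):
            AccelerationParams(5.0, 5.0, OffsetVector.zeros(("a",)))
        with pytest.raises(ValueError):
            AccelerationParams(5.0, -5.0, OffsetVector.zeros(("a",)))

    @given(st.floats(-600, 200))
    def test_boost_laws(self, h_r):
        hs, sl = aeds_boost(h_r, self.PARAMS)
        assert hs <= h_r + 1e-9
        assert 0.0 <= sl <= 1.0
        if h_r <= self.PARAMS.e_min:
            assert hs == h_r
        else:
            assert hs < h_r
        # non-decreasing
        hs2, _ = aeds_boost(h_r + 1e-3, self.PARAMS)
        assert hs2 >= hs - 1e-12

    @pytest.mark.parametrize("edge", [-435.0, 64.54])
    def test_c1_continuity_at_thresholds(self, edge):
        eps = 1e-6
        below, sb = aeds_boost(edge - eps, self.PARAMS)
        above, sa = aeds_boost(edge + eps, self.PARAMS)
        assert above - below == pytest.approx(sb * 2 * eps, abs=1e-9)
        assert sa == pytest.approx(sb, abs=1e-5)

    def test_slope_matches_finite_difference(self):
        for h_r in (-300.0, -100.0, 0.0, 50.0):
            hs, sl = aeds_boost(h_r, self.PARAMS)
            fd = (aeds_boost(h_r + 1e-5, self.PARAMS)[0] - aeds_boost(h_r - 1e-5, self.PARAMS)[0]) / 2e-5
            assert sl == pytest.approx(fd, abs=1e-6)


class TestBoostedForce:
    def _fd_force(self, system, x, params, h=1e-5):
        f = np.empty(len(x))
        ids = system.endstate_ids
        off = params.offsets.aligned(ids)
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            hp = aeds_boost(eds_reference_energy(system.endstate_energies(xp), off, CTX), params)[0]
            hm = aeds_boost(eds_reference_energy(system.endstate_energies(xm), off, CTX), params)[0]
            vp = vm = 0.0
            if system.restraint is not None:
                vp = system.restraint_energy_and_gradient(xp)[0]
                vm = system.restraint_energy_and_gradient(xm)[0]
            f[j] = -((hp + vp) - (hm + vm)) / (2 * h)
        return f

    def test_matches_finite_differences_everywhere(self):
        system = make_t4l_like_toy(2, barrier=10.0, preference_split=1, seed=3)
        g = oracle_free_energies(system, CTX).free_energies
        off = OffsetVector.from_values(system.endstate_ids, g - g[0])
        params = AccelerationParams(-8.0, 12.0, off)
        # interior points, the inter-state barrier top, and the phi barrier
        points = [np.array([-1.0, 180.0]), np.array([0.0, 180.0]), np.array([1.0, -60.0]),
                  np.array([0.3, 60.0]), np.array([2.5, 100.0])]
        for x in points:
            force, h_r, h_star, v_restr = boosted_force(system, x, params, CTX)
            fd = self._fd_force(system, x, params)
            np.testing.assert_allclose(force, fd, rtol=1e-5, atol=1e-7)

    def test_zero_force_above_e_max(self):
        system = make_t4l_like_toy(2, barrier=10.0, preference_split=1, seed=3, restrain=False)
        params = AccelerationParams(-1000.0, -900.0, OffsetVector.zeros(system.endstate_ids))
        force, h_r, h_star, _ = boosted_force(system, np.array([0.0, 60.0]), params, CTX)
        assert h_r > params.e_max
        np.testing.assert_allclose(force, 0.0, atol=1e-12)

    def test_single_harmonic_reduces_to_plain_gradient(self, harmonic_1d):
        params = AccelerationParams(1e5, 2e5, OffsetVector.zeros(("s01",)))
        x = np.array([0.7])
        force, *_ = boosted_force(harmonic_1d, x, params, CTX)
        assert force[0] == pytest.approx(-10.0 * 0.7, rel=1e-12)

    def test_rejects_out_of_domain(self, harmonic_1d):
        params = AccelerationParams(-1.0, 1.0, OffsetVector.zeros(("s01",)))
        with pytest.raises(ValueError):
            boosted_force(harmonic_1d, np.array([99.0]), params, CTX)


class TestOffsetVector:
    def test_anchor_must_be_zero(self):
        with pytest.raises(ValueError):
            OffsetVector(("a", "b"), np.array([1.0, 0.0]), "a")
        ov = OffsetVector.from_values(("a", "b"), [1.0, 3.0], "a")
        assert ov["a"] == 0.0
        assert ov["b"] == 2.0

    def test_alignment_by_id(self):
        ov = OffsetVector.from_values(("a", "b", "c"), [0.0, 1.0, 2.0])
        np.testing.assert_allclose(ov.aligned(("c", "a", "b")), [2.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            ov.aligned(("a", "zz"))
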