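"""Free-energy estimators and sampling diagnostics on crafted and toy data."""

import numpy as np
import pytest

from aedskit import (
    AccelerationParams,
    EnergyTrajectory,
    OffsetVector,
    SimulationConfig,
    ThermoContext,
    apply_restraint_correction,
    contributing_frames,
    frame_weight_fractions,
    reweight_observable,
    sampling_stats,
    screening_rank,
    simulate,
    zwanzig_dG,
    make_t4l_like_toy,
    oracle_free_energies,
)
from aedskit.estimators import UnsupportedEndstateWarning, free_energy_report

CTX = ThermoContext(300.0)
RT = CTX.RT


def crafted(h, h_star=None, v_restr=None, ids=None):
    """Build a trajectory directly from an energy matrix."""
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    ids = ids or tuple(f"s{k + 1:02d}" for k in range(h.shape[1]))
    h_star = np.zeros(n) if h_star is None else np.asarray(h_star, float)
    v_restr = np.zeros(n) if v_restr is None else np.asarray(v_restr, float)
    return EnergyTrajectory(
        ids=ids, time=np.arange(n, dtype=float), h=h,
        h_r=h_star.copy(), h_star=h_star, v_restr=v_restr,
    )


class TestZwanzig:
    def test_self_consistency_is_exactly_zero(self):
        h_star = np.array([3.0, -1.0, 0.5])
        traj = crafted(h_star[:, None], h_star=h_star)
        assert zwanzig_dG(traj, "s01", CTX) == pytest.approx(0.0, abs=1e-13)

    def test_constant_gap_identity(self):
        h_star = np.array([-2.0, 1.0, 4.0, 0.0])
        c = 3.7
        traj = crafted((h_star + c)[:, None], h_star=h_star)
        assert zwanzig_dG(traj, "s01", CTX) == pytest.approx(c, abs=1e-12)

    def test_unsupported_endstate_warns_and_returns_inf(self):
        # an endstate with literally zero weight in every frame
        h = np.column_stack([np.zeros(5), np.full(5, np.inf)])
        traj = crafted(h, h_star=np.zeros(5))
        with pytest.warns(UnsupportedEndstateWarning):
            assert zwanzig_dG(traj, "s02", CTX) == np.inf
        # a large-but-finite gap stays finite (log-sum-exp never underflows)
        h2 = np.column_stack([np.zeros(5), np.full(5, 1e6)])
        assert np.isfinite(zwanzig_dG(crafted(h2, h_star=np.zeros(5)), "s02", CTX))

    def test_toy_ddg_matches_quadrature_oracle(self):
        system = make_t4l_like_toy(2, barrier=6.0, preference_split=1, seed=7)
        g = oracle_free_energies(system, CTX).free_energies
        off = OffsetVector.from_values(system.endstate_ids, g - g[0])
        params = AccelerationParams(-6.0, 16.0, off)
        dds = []
        for seed in range(4):
            traj = simulate(system, params, SimulationConfig(n_steps=60000, stride=1, seed=50 + seed))
            traj = apply_restraint_correction(traj)
            dds.append(zwanzig_dG(traj, "s02", CTX) - zwanzig_dG(traj, "s01", CTX))
        dds = np.array(dds)
        se = dds.std(ddof=1) / 2.0
        assert abs(dds.mean() - (g[1] - g[0])) < max(0.5, 3.0 * se)


class TestRestraintCorrection:
    def test_identity_when_restraint_zero(self):
        traj = crafted(np.zeros((4, 1)), h_star=np.array([1.0, 2.0, 0.0, -1.0]))
        corrected = apply_restraint_correction(traj)
        np.testing.assert_array_equal(corrected.h_sampled, traj.h_sampled)

    def test_constant_restraint_shifts_dg_by_minus_c(self):
        h_star = np.array([-2.0, 1.0, 4.0, 0.0])
        traj = crafted(h_star[:, None], h_star=h_star, v_restr=np.full(4, 1.5))
        before = zwanzig_dG(traj, "s01", CTX)
        after = zwanzig_dG(apply_restraint_correction(traj), "s01", CTX)
        assert after - before == pytest.approx(-1.5, abs=1e-12)

    def test_restrained_and_free_toys_agree_after_correction(self):
        free = make_t4l_like_toy(2, barrier=4.0, preference_split=1, seed=5, restrain=False)
        restrained = make_t4l_like_toy(2, barrier=4.0, preference_split=1, seed=5, restrain=True)
        g = oracle_free_energies(free, CTX).free_energies
        off = OffsetVector.from_values(free.endstate_ids, g - g[0])
        params = AccelerationParams(-6.0, 16.0, off)
        dd = {}
        for name, system in (("free", free), ("restrained", restrained)):
            vals = []
            for seed in range(4):
                traj = simulate(system, params, SimulationConfig(n_steps=40000, stride=1, seed=70 + seed))
                traj = apply_restraint_correction(traj)
                vals.append(zwanzig_dG(traj, "s02", CTX) - zwanzig_dG(traj, "s01", CTX))
            dd[name] = np.array(vals)
        se = np.sqrt(dd["free"].var(ddof=1) / 4 + dd["restrained"].var(ddof=1) / 4)
        assert abs(dd["free"].mean() - dd["restrained"].mean()) < 3.0 * max(se, 0.05)


class TestSamplingStats:
    def test_constant_assignment(self):
        h = np.column_stack([np.zeros(10), np.ones(10)])
        fr, tr = sampling_stats(crafted(h), OffsetVector.zeros(("s01", "s02")))
        np.testing.assert_allclose(fr, [100.0, 0.0])
        assert tr == 0

    def test_strict_alternation_counts_nine_transitions(self):
        h = np.zeros((10, 2))
        h[::2, 0], h[1::2, 1] = -1.0, -1.0
        fr, tr = sampling_stats(crafted(h), OffsetVector.zeros(("s01", "s02")))
        np.testing.assert_allclose(fr, [50.0, 50.0])
        assert tr == 9

    def test_ties_break_to_lowest_index(self):
        h = np.zeros((5, 3))
        fr, tr = sampling_stats(crafted(h), OffsetVector.zeros(("s01", "s02", "s03")))
        np.testing.assert_allclose(fr, [100.0, 0.0, 0.0])

    def test_assignment_and_weight_fractions_agree_when_separated(self, two_state_toy):
        g = oracle_free_energies(two_state_toy, CTX).free_energies
        off = OffsetVector.from_values(two_state_toy.endstate_ids, g - g[0])
        params = AccelerationParams(-6.0, 16.0, off)
        traj = simulate(two_state_toy, params, SimulationConfig(n_steps=40000, stride=1, seed=8))
        fr, _ = sampling_stats(traj, off)
        wf = frame_weight_fractions(traj, off, CTX)
        assert np.all(np.abs(fr - wf) < 10.0)


class TestWeightFractions:
    def test_symmetric_and_single(self):
        h = np.zeros((6, 2))
        np.testing.assert_allclose(
            frame_weight_fractions(crafted(h), OffsetVector.zeros(("s01", "s02")), CTX), [50.0, 50.0]
        )
        np.testing.assert_allclose(
            frame_weight_fractions(crafted(np.zeros((6, 1))), OffsetVector.zeros(("s01",)), CTX), [100.0]
        )

    def test_alternating_ten_rt_gaps_match_logistic_average(self):
        gap = 10.0 * RT
        h = np.zeros((4, 2))
        h[:2, 1], h[2:, 0] = gap, gap
        frac = frame_weight_fractions(crafted(h), OffsetVector.zeros(("s01", "s02")), CTX)
        p = 1.0 / (1.0 + np.exp(-10.0))
        np.testing.assert_allclose(frac, [100 * 0.5, 100 * 0.5], atol=1e-10)
        w_lo = 1.0 / (1.0 + np.exp(-10.0))
        assert frac[0] == pytest.approx(100 * (0.5 * w_lo + 0.5 * (1 - w_lo)), abs=1e-9)

    def test_fractions_sum_to_100(self, two_state_toy):
        off = OffsetVector.zeros(two_state_toy.endstate_ids)
        params = AccelerationParams(-6.0, 16.0, off)
        traj = simulate(two_state_toy, params, SimulationConfig(n_steps=2000, stride=1, seed=3))
        assert frame_weight_fractions(traj, off, CTX).sum() == pytest.approx(100.0, abs=1e-9)
        fr, _ = sampling_stats(traj, off)
        assert fr.sum() == pytest.approx(100.0, abs=0.1)


class TestContributingFrames:
    def test_degenerate_identities(self):
        h_star = np.array([0.0, 1.0, -2.0])
        traj = crafted(h_star[:, None], h_star=h_star)
        assert contributing_frames(traj, "s01", 0.0, CTX) == 100.0
        traj_c = crafted((h_star + 5.0)[:, None], h_star=h_star)
        assert contributing_frames(traj_c, "s01", 5.0, CTX) == 100.0

    def test_matches_independent_brute_force_loop(self, two_state_toy):
        off = OffsetVector.zeros(two_state_toy.endstate_ids)
        params = AccelerationParams(-6.0, 16.0, off)
        traj = simulate(two_state_toy, params, SimulationConfig(n_steps=10000, stride=2, seed=13))
        traj = apply_restraint_correction(traj)
        for sid in two_state_toy.endstate_ids:
            dg = zwanzig_dG(traj, sid, CTX)
            count = 0
            for t in range(traj.n_frames):  # independent explicit loop
                gap = traj.column(sid)[t] - (traj.h_star[t] + traj.v_restr[t])
                if gap < dg + RT:
                    count += 1
            assert contributing_frames(traj, sid, dg, CTX) == pytest.approx(
                100.0 * count / traj.n_frames, abs=1e-12
            )


class TestReweightObservable:
    def test_constant_observable_returns_constant(self):
        h = np.column_stack([np.zeros(8), np.linspace(-1, 1, 8)])
        traj = crafted(h, h_star=np.zeros(8))
        for sid in ("s01", "s02"):
            assert reweight_observable(traj, np.full(8, 2.5), sid, CTX) == pytest.approx(2.5)

    def test_single_endstate_zero_boost_is_plain_average(self):
        h_star = np.array([0.0, 1.0, 2.0, 3.0])
        traj = crafted(h_star[:, None], h_star=h_star)
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert reweight_observable(traj, obs, "s01", CTX) == pytest.approx(obs.mean())

    def test_unsupported_endstate_yields_nan_with_warning(self):
        h = np.column_stack([np.zeros(5), np.full(5, np.inf)])
        traj = crafted(h, h_star=np.zeros(5))
        with pytest.warns(UnsupportedEndstateWarning):
            assert np.isnan(reweight_observable(traj, np.ones(5), "s02", CTX))


class TestScreeningRank:
    def test_tie_rule_and_sort_contract(self):
        h = np.zeros((10, 3))  # all ties → all frames to s01
        rank = screening_rank(crafted(h), OffsetVector.zeros(("s01", "s02", "s03")))
        assert [r[0] for r in rank] == ["s01", "s02", "s03"]

    def test_descending_fraction_pattern(self):
        # fractions engineered to 47 / 27 / 14 / 12 percent
        n = 100
        h = np.zeros((n, 4))
        bounds = [0, 47, 74, 88, 100]
        for k in range(4):
            h[bounds[k] : bounds[k + 1], :] = 1.0
            h[bounds[k] : bounds[k + 1], k] = 0.0
        rank = screening_rank(crafted(h), OffsetVector.zeros(tuple(f"s{k+1:02d}" for k in range(4))))
        assert [r[0] for r in rank] == ["s01", "s02", "s03", "s04"]
        np.testing.assert_allclose([r[1] for r in rank], [47.0, 27.0, 14.0, 12.0])


class TestReport:
    def test_report_aggregates_replicates(self, two_state_toy):
        g = oracle_free_energies(two_state_toy, CTX).free_energies
        off = OffsetVector.from_values(two_state_toy.endstate_ids, g - g[0])
        params = AccelerationParams(-6.0, 16.0, off)
        trajs = [
            simulate(two_state_toy, params, SimulationConfig(n_steps=20000, stride=2, seed=s))
            for s in range(3)
        ]
        result = free_energy_report(trajs, off, CTX)
        assert result.n_replicates == 3
        assert result.sampling.sum() == pytest.approx(100.0, abs=0.1)
        assert np.all((result.contributing >= 0) & (result.contributing <= 100))
        assert np.all(np.isfinite(result.se))
        assert result.ddg("s01", "s02") == pytest.approx(-result.ddg("s02", "s01"), abs=1e-12)
        d = result.as_dict()
        assert set(d) >= {"endstates", "dG_kJ_per_mol", "transitions"}
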