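"""Free energies and sampling diagnostics from energy trajectories.

The central estimator is the Zwanzig (exponential-averaging) formula
applied from the sampled reference ensemble to each endstate:

    ΔG_iR = −RT · ln ⟨ exp(−(H_i − H_sampled)/RT) ⟩,

with H_sampled the boosted reference energy H* plus, after restraint
correction, the restraint energy. Pairwise differences
ΔΔG_ij = ΔG_jR − ΔG_iR are reference-free and antisymmetric by
construction.

Diagnostics mirror the standard quality checks for reference-state
simulations: per-endstate sampling fractions (by lowest offset-corrected
energy, or by Boltzmann weights), transition counts, and the fraction of
frames that actually support each endstate's free energy (energy gap below
ΔG + RT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .dynamics import EnergyTrajectory
from .hamiltonian import OffsetVector, endstate_weights
from .thermo import ThermoContext

__all__ = [
    "FreeEnergyResult",
    "apply_restraint_correction",
    "zwanzig_dG",
    "ddG",
    "sampling_stats",
    "frame_weight_fractions",
    "contributing_frames",
    "reweight_observable",
    "screening_rank",
    "free_energy_report",
]


class UnsupportedEndstateWarning(UserWarning):
    """The sampled ensemble carries no statistical weight for an endstate."""


@dataclass(frozen=True)
class FreeEnergyResult:
    """Per-endstate free energies relative to the sampled reference state."""

    ids: tuple[str, ...]
    dg: np.ndarray  # ΔG_iR, kJ·mol⁻¹ (mean over replicates)
    se: np.ndarray  # standard error over replicates
    contributing: np.ndarray  # % of frames supporting each endstate
    sampling: np.ndarray  # % of frames assigned to each endstate
    transitions: int
    n_replicates: int = 1

    def ddg(self, i: str, j: str) -> float:
        """ΔΔG_ij = ΔG_jR − ΔG_iR."""
        ids = list(self.ids)
        return float(self.dg[ids.index(j)] - self.dg[ids.index(i)])

    def as_dict(self) -> dict:
        return {
            "endstates": list(self.ids),
            "dG_kJ_per_mol": [float(v) for v in self.dg],
            "standard_error": [float(v) for v in self.se],
            "contributing_percent": [float(v) for v in self.contributing],
            "sampling_percent": [float(v) for v in self.sampling],
            "transitions": int(self.transitions),
            "n_replicates": int(self.n_replicates),
        }


def apply_restraint_correction(traj: EnergyTrajectory) -> EnergyTrajectory:
    """Fold the restraint energy into the sampled reference energy.

    Returns a view of the trajectory in which reweighting uses
    H* + V_restr as the sampled Hamiltonian; endstate energies are
    untouched. Idempotent, and the identity when V_restr is 0 everywhere.
    """
    return replace(traj, restraint_corrected=True)


def zwanzig_dG(traj: EnergyTrajectory, endstate_id: str, ctx: ThermoContext) -> float:
    """Free energy of one endstate relative to the sampled reference state.

    Computed as a log-sum-exp over frames minus ln(n_frames), so it is
    finite whenever at least one frame has a finite exponent. Returns +inf
    (with a warning) when no frame supports the endstate.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    gap = traj.column(endstate_id) - traj.h_sampled
    a = -gap / ctx.RT
    lse = logsumexp(a)
    if not np.isfinite(lse):
        warnings.warn(
            f"endstate {endstate_id!r} unsupported by the sampled ensemble",
            UnsupportedEndstateWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(-ctx.RT * (lse - np.log(traj.n_frames)))


def ddG(traj: EnergyTrajectory, i: str, j: str, ctx: ThermoContext) -> float:
    """Pairwise free-energy difference ΔΔG_ij = ΔG_jR − ΔG_iR."""
    return zwanzig_dG(traj, j, ctx) - zwanzig_dG(traj, i, ctx)


def _assignments(traj: EnergyTrajectory, offsets: OffsetVector) -> np.ndarray:
    off = offsets.aligned(traj.ids)
    # argmin breaks ties toward the lowest endstate index (deterministic)
    return np.argmin(traj.h - off, axis=1)


def sampling_stats(traj: EnergyTrajectory, offsets: OffsetVector):
    """Sampling fraction (%) per endstate and the number of transitions.

    Each frame is assigned to the endstate minimizing H_i − ΔF_i^R; a
    transition is a change of assignment between consecutive frames.
    """
    a = _assignments(traj, offsets)
    counts = np.bincount(a, minlength=len(traj.ids)).astype(float)
    fractions = 100.0 * counts / len(a)
    transitions = int(np.count_nonzero(np.diff(a)))
    return fractions, transitions


def frame_weight_fractions(
    traj: EnergyTrajectory, offsets: OffsetVector, ctx: ThermoContext
) -> np.ndarray:
    """Sampling fractions (%) from mean Boltzmann endstate weights.

    Softer than lowest-energy assignment: frames where several endstates
    have comparable energies contribute to each of them. Reduces to
    ``sampling_stats`` fractions in the zero-temperature limit.
    """
    w = endstate_weights(traj.h, offsets.aligned(traj.ids), ctx)
    return 100.0 * w.mean(axis=0)


def contributing_frames(
    traj: EnergyTrajectory, endstate_id: str, dg: float, ctx: ThermoContext
) -> float:
    """Percent of frames whose endstate-vs-reference gap is below ΔG + RT."""
    gap = traj.column(endstate_id) - traj.h_sampled
    return 100.0 * float(np.count_nonzero(gap < dg + ctx.RT)) / traj.n_frames


def reweight_observable(
    traj: EnergyTrajectory, observable, endstate_id: str, ctx: ThermoContext
) -> float:
    """Expectation of a per-frame observable under one endstate's ensemble.

    ⟨A⟩_i = Σ_t A(t) u_i(t) / Σ_t u_i(t) with u_i ∝ exp(−(H_i − H_sampled)/RT),
    evaluated with shifted exponentials for stability. Applied to
    well-membership indicators this yields per-endstate conformational
    populations from a single reference-state run.
    """
    a_vals = np.asarray(observable, dtype=float)
    if a_vals.shape != (traj.n_frames,):
        raise ValueError("observable must provide one value per frame")
    log_u = -(traj.column(endstate_id) - traj.h_sampled) / ctx.RT
    m = np.max(log_u)
    if not np.isfinite(m):
        warnings.warn(
            f"endstate {endstate_id!r} unsupported by the sampled ensemble",
            UnsupportedEndstateWarning,
            stacklevel=2,
        )
        return float("nan")
    u = np.exp(log_u - m)
    return float(np.sum(a_vals * u) / np.sum(u))


def screening_rank(traj: EnergyTrajectory, offsets: OffsetVector):
    """Endstates ranked by descending sampling fraction (ties by index).

    Under deliberately unequalized offsets (e.g. solvent-stage offsets in
    the bound stage) the most sampled endstates are the strongest binders,
    which turns a single reference run into a fast affinity screen.
    """
    fractions, _ = sampling_stats(traj, offsets)
    order = sorted(range(len(traj.ids)), key=lambda k: (-fractions[k], k))
    return [(traj.ids[k], float(fractions[k])) for k in order]


def free_energy_report(
    trajs, offsets: OffsetVector, ctx: ThermoContext, *, restraint_correction: bool = True
) -> FreeEnergyResult:
    """Aggregate free energies and diagnostics over replicate trajectories.

    ΔG_iR is averaged over replicates and its standard error estimated
    from the replicate scatter (SE = s/√n); sampling and contributing
    fractions are replicate means; transitions are summed.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    ids = trajs[0].ids
    if restraint_correction:
        trajs = [apply_restraint_correction(t) for t in trajs]
    per_rep = np.array([[zwanzig_dG(t, i, ctx) for i in ids] for t in trajs])
    dg = per_rep.mean(axis=0)
    if len(trajs) > 1:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(len(trajs))
    else:
        se = np.full(len(ids), np.nan)
    contrib = np.array(
        [
            np.mean([contributing_frames(t, i, per_rep[r, k], ctx) for r, t in enumerate(trajs)])
            for k, i in enumerate(ids)
        ]
    )
    samp = np.mean([sampling_stats(t, offsets)[0] for t in trajs], axis=0)
    transitions = int(np.sum([sampling_stats(t, offsets)[1] for t in trajs]))
    return FreeEnergyResult(
        ids=ids,
        dg=dg,
        se=se,
        contributing=contrib,
        sampling=samp,
        transitions=transitions,
        n_replicates=len(trajs),
    )
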