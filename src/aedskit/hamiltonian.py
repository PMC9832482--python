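"""EDS reference-state Hamiltonian and the AEDS boosting potential.

The enveloping distribution sampling (EDS) reference state combines N
endstate Hamiltonians H_i with per-endstate energy offsets ΔF_i^R into

    H_R = −RT · ln Σ_i exp(−(H_i − ΔF_i^R)/RT),

which places all endstate minima at a common level when the offsets equal
the endstate free energies. Accelerated EDS (AEDS) additionally applies a
harmonic boosting potential to H_R between two energy thresholds E_min and
E_max, pulling energy maxima down without distorting the minima:

    H* = H_R                                       for H_R ≤ E_min
    H* = H_R − (H_R − E_min)² / (2 (E_max − E_min)) for E_min < H_R ≤ E_max
    H* = (E_min + E_max)/2                          for H_R > E_max.

The third branch is the C¹ continuation of the harmonic branch, so H* is
continuous and once differentiable everywhere and non-decreasing in H_R.

Everything here is pure computation on arrays; the dynamics and estimator
modules consume these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .thermo import ThermoContext

__all__ = [
    "OffsetVector",
    "AccelerationParams",
    "eds_reference_energy",
    "aeds_boost",
    "endstate_weights",
    "boosted_force",
]


@dataclass(frozen=True)
class OffsetVector:
    """Per-endstate energy offsets ΔF_i^R with a fixed-gauge anchor.

    The anchor endstate's offset is identically zero; all other offsets are
    reported relative to it (offsets are only defined up to a common
    constant, which cancels in the reference state up to an additive shift).

    Parameters
    ----------
    ids : tuple of str
        Endstate identifiers, in column order.
    values : ndarray
        Offset of each endstate in kJ·mol⁻¹.
    anchor : str
        Identifier of the endstate whose offset is fixed to 0.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    anchor: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.ids):
            raise ValueError("offsets must be a 1-D array matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate endstate ids")
        if self.anchor not in self.ids:
            raise ValueError(f"anchor {self.anchor!r} not among endstate ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("offsets must be finite")
        if values[self.ids.index(self.anchor)] != 0.0:
            raise ValueError("anchor offset must be exactly 0")

    @classmethod
    def zeros(cls, ids, anchor: str | None = None) -> "OffsetVector":
        ids = tuple(ids)
        return cls(ids, np.zeros(len(ids)), anchor or ids[0])

    @classmethod
    def from_values(cls, ids, values, anchor: str | None = None) -> "OffsetVector":
        """Build an offset vector, re-gauging so the anchor offset is 0."""
        ids = tuple(ids)
        anchor = anchor or ids[0]
        values = np.asarray(values, dtype=float)
        values = values - values[ids.index(anchor)]
        return cls(ids, values, anchor)

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, endstate_id: str) -> float:
        return float(self.values[self.ids.index(endstate_id)])

    def as_dict(self) -> dict[str, float]:
        return {i: float(v) for i, v in zip(self.ids, self.values)}

    def aligned(self, ids) -> np.ndarray:
        """Offsets reordered to match ``ids``; error on unknown id."""
        return np.array([self[i] for i in ids])


@dataclass(frozen=True)
class AccelerationParams:
    """The AEDS control set: boost thresholds and endstate offsets."""

    e_min: float
    e_max: float
    offsets: OffsetVector

    def __post_init__(self) -> None:
        if not (self.e_min < self.e_max):
            raise ValueError(
                f"E_min must be strictly below E_max (got {self.e_min} ≥ {self.e_max})"
            )


def _validated_energies(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.size == 0 or h.shape[-1] == 0:
        raise ValueError("frame must contain at least one endstate energy")
    if not np.all(np.isfinite(h)):
        raise ValueError("endstate energies must be finite")
    return h


def eds_reference_energy(
    h: np.ndarray, offsets: OffsetVector | np.ndarray, ctx: ThermoContext
) -> np.ndarray | float:
    """EDS reference-state energy H_R for one frame or a batch of frames.

    Parameters
    ----------
    h : array, shape (N,) or (n_frames, N)
        Endstate potential energies H_i in kJ·mol⁻¹. Restraint energies are
        *not* part of H_R; they are handled during free-energy analysis.
    offsets : OffsetVector or array
        ΔF_i^R aligned with the columns of ``h``.
    ctx : ThermoContext

    Returns
    -------
    float or ndarray
        H_R = −RT·ln Σ_i exp(−(H_i − ΔF_i^R)/RT), evaluated with a
        numerically stable log-sum-exp. Satisfies
        H_R ≤ min_i(H_i − ΔF_i^R).
    """
    h = _validated_energies(h)
    off = offsets.values if isinstance(offsets, OffsetVector) else np.asarray(offsets, float)
    if off.shape[-1] != h.shape[-1]:
        raise ValueError("offsets do not cover every endstate in the frame")
    a = -(h - off) / ctx.RT
    out = -ctx.RT * logsumexp(a, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def endstate_weights(
    h: np.ndarray, offsets: OffsetVector | np.ndarray, ctx: ThermoContext
) -> np.ndarray:
    """Boltzmann weights w_i of each endstate in the reference ensemble.

    w_i ∝ exp(−(H_i − ΔF_i^R)/RT), normalized to sum to 1 per frame. The
    argmax of w coincides with the argmin of H_i − ΔF_i^R.
    """
    h = _validated_energies(h)
    off = offsets.values if isinstance(offsets, OffsetVector) else np.asarray(offsets, float)
    if off.shape[-1] != h.shape[-1]:
        raise ValueError("offsets do not cover every endstate in the frame")
    a = -(h - off) / ctx.RT
    a = a - np.max(a, axis=-1, keepdims=True)
    e = np.exp(a)
    return e / np.sum(e, axis=-1, keepdims=True)


def aeds_boost(h_r, params: AccelerationParams):
    """Apply the AEDS harmonic boosting potential to a reference energy.

    Returns ``(h_star, dh_star_dh_r)``: the boosted energy and the
    derivative of the boosted energy with respect to H_R (the factor by
    which forces on the coordinates are scaled).

    Works elementwise on scalars or arrays.
    """
    e_min, e_max = params.e_min, params.e_max
    span = e_max - e_min
    h_r_arr = np.asarray(h_r, dtype=float)
    below = h_r_arr <= e_min
    above = h_r_arr > e_max
    band = ~below & ~above
    h_star = np.where(below, h_r_arr, 0.0)
    slope = np.where(below, 1.0, 0.0)
    h_star = np.where(band, h_r_arr - (h_r_arr - e_min) ** 2 / (2.0 * span), h_star)
    slope = np.where(band, 1.0 - (h_r_arr - e_min) / span, slope)
    h_star = np.where(above, 0.5 * (e_min + e_max), h_star)
    if np.ndim(h_r) == 0:
        return float(h_star), float(slope)
    return h_star, slope


def boosted_force(system, x, params: AccelerationParams, ctx: ThermoContext):
    """Force −∇H* on the coordinates of a toy system at configuration x.

    By the chain rule, ∇H* = (dH*/dH_R) Σ_i w_i ∇H_i, with w_i the
    endstate weights at x. If the system defines a restraint its force is
    added with unit weight (the restraint acts on the sampled Hamiltonian,
    outside the boost).

    Returns ``(force, h_r, h_star, v_restr)`` so dynamics can reuse the
    energies without re-evaluating the system.
    """
    x = np.asarray(x, dtype=float)
    system.validate_coords(x)
    h, grads = system.endstate_energies_and_gradients(x)
    off = params.offsets.aligned(system.endstate_ids)
    w = endstate_weights(h, off, ctx)
    h_r = eds_reference_energy(h, off, ctx)
    h_star, slope = aeds_boost(h_r, params)
    force = -slope * (w @ grads)
    v_restr = 0.0
    if system.restraint is not None:
        vr, gr = system.restraint_energy_and_gradient(x)
        force = force - gr
        v_restr = vr
    return force, h_r, h_star, v_restr
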