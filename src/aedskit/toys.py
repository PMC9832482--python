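"""Analytic multi-endstate toy systems with quadrature oracles.

These systems emulate the statistical structure of a multi-ligand
binding-site problem: each endstate ("ligand") is a distinct minimum along
a *binding coordinate* x, and a slow *orthogonal coordinate* φ (periodic,
degrees) carries two metastable wells — trans at 180° and gauche at −60°,
the χ₁ convention of a valine side chain — whose relative depth depends on
the endstate. Bulky, strongly binding endstates prefer gauche; the rest
prefer trans. High φ barriers make the orthogonal coordinate the slow
degree of freedom that enhanced sampling must conquer.

All endstate potentials are sums of univariate terms, so configuration
integrals factorize over coordinates and exact free energies and well
populations are available by 1-D adaptive quadrature. These exact values
are the test oracle for every estimator in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .thermo import ThermoContext

__all__ = [
    "Coordinate",
    "Harmonic",
    "TwoWell",
    "WellPreference",
    "FlatBottomRestraint",
    "EndState",
    "ToySystem",
    "OracleResult",
    "make_t4l_like_toy",
    "exact_free_energy",
    "exact_orthogonal_populations",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class Coordinate:
    """A named degree of freedom.

    ``friction`` is the coordinate's Langevin friction γ_c, in the reduced
    unit system of the dynamics module; it sets the mobility Δt/γ_c of the
    coordinate. Periodic coordinates are measured in degrees and wrapped to
    (lo, hi]; linear coordinates use their bounds as the system domain.
    """

    name: str
    kind: str = "linear"  # "linear" | "periodic"
    lo: float = -10.0
    hi: float = 10.0
    friction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "periodic"):
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if not (self.lo < self.hi):
            raise ValueError("coordinate bounds must satisfy lo < hi")
        if not (self.friction > 0):
            raise ValueError("friction must be positive")

    @property
    def period(self) -> float:
        return self.hi - self.lo

    def wrap(self, value: float) -> float:
        if self.kind != "periodic":
            return value
        return (value - self.lo) % self.period + self.lo


@dataclass(frozen=True)
class Harmonic:
    """½ k (x − center)² on a linear coordinate."""

    coord: str
    center: float
    k: float


@dataclass(frozen=True)
class TwoWell:
    """Periodic double well with minima at the trans and gauche positions.

    V(φ) = B · (1 − b_t(φ) − b_g(φ)),  b_w(φ) = exp(κ (cos(φ − φ_w) − 1)).

    Each well bottom sits near 0 and the inter-well plateau near B, so B is
    the barrier height (measured from an unpreferred well bottom). κ sets
    the well width; at κ = 6 the two wells overlap negligibly.
    """

    coord: str
    barrier: float
    kappa: float = 6.0
    well_trans: float = 180.0
    well_gauche: float = -60.0


@dataclass(frozen=True)
class WellPreference:
    """Endstate-specific tilt of the two-well coordinate.

    V(φ) = −ε · σ_w(φ) where σ_w is a smooth indicator of the preferred
    well's basin (a tanh switch across the two inter-well midpoints, ±1
    almost everywhere except near the barrier tops). Because the tilt is
    essentially constant inside each basin, it changes well populations by
    the two-state Boltzmann factor exp(ε/RT) without reshaping the wells.
    """

    coord: str
    eps: float
    well: str = "gauche"  # which well is favored
    sharpness: float = 4.0
    boundary: float = 60.0  # midpoint between the wells, degrees

    def __post_init__(self) -> None:
        if self.well not in ("trans", "gauche"):
            raise ValueError("preference well must be 'trans' or 'gauche'")


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Zero inside |x − center| ≤ half_width, harmonic ½k(excess)² outside.

    The toy analogue of weak binding-site restraints: it confines the
    binding coordinate without touching the region where the endstate
    minima live. Its energy is recorded per frame and folded into the
    sampled Hamiltonian during free-energy analysis.
    """

    coord: str
    center: float
    half_width: float
    k: float

    def energy(self, x):
        excess = np.maximum(np.abs(np.asarray(x, float) - self.center) - self.half_width, 0.0)
        return 0.5 * self.k * excess**2

    def gradient(self, x):
        d = np.asarray(x, float) - self.center
        excess = np.maximum(np.abs(d) - self.half_width, 0.0)
        return self.k * excess * np.sign(d)


@dataclass(frozen=True)
class EndState:
    """One endstate Hamiltonian: a constant depth plus univariate terms."""

    id: str
    depth: float
    terms: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise ValueError("endstate needs at least one potential term")


# ---------------------------------------------------------------------------
# Vectorized term blocks: one block evaluates one term slot for all
# endstates at once, which keeps the per-step cost of dynamics low.
# ---------------------------------------------------------------------------


class _HarmonicBlock:
    def __init__(self, coord_index, terms):
        self.j = coord_index
        self.c = np.array([t.center for t in terms])
        self.k = np.array([t.k for t in terms])

    def energy(self, x):
        return 0.5 * self.k * (x - self.c) ** 2

    def gradient(self, x):
        return self.k * (x - self.c)

    def energy_and_gradient(self, x):
        d = x - self.c
        kd = self.k * d
        return 0.5 * kd * d, kd

    def energy_batch(self, x):
        return 0.5 * self.k[None, :] * (x[:, None] - self.c[None, :]) ** 2


class _TwoWellBlock:
    def __init__(self, coord_index, terms):
        self.j = coord_index
        self.B = np.array([t.barrier for t in terms])
        t0 = terms[0]
        if any((t.kappa, t.well_trans, t.well_gauche) != (t0.kappa, t0.well_trans, t0.well_gauche) for t in terms):
            raise ValueError("two-well geometry must be shared across endstates")
        self.kappa = t0.kappa
        self.wt = t0.well_trans
        self.wg = t0.well_gauche

    def _bumps(self, phi):
        dt = (np.asarray(phi, float) - self.wt) * _DEG
        dg = (np.asarray(phi, float) - self.wg) * _DEG
        return np.exp(self.kappa * (np.cos(dt) - 1.0)), np.exp(self.kappa * (np.cos(dg) - 1.0)), dt, dg

    def energy(self, phi):
        bt, bg, _, _ = self._bumps(phi)
        return self.B * (1.0 - bt - bg)

    def gradient(self, phi):
        bt, bg, dt, dg = self._bumps(phi)
        return self.B * self.kappa * _DEG * (np.sin(dt) * bt + np.sin(dg) * bg)

    def energy_and_gradient(self, phi):
        bt, bg, dt, dg = self._bumps(phi)
        e = self.B * (1.0 - bt - bg)
        g = self.B * self.kappa * _DEG * (np.sin(dt) * bt + np.sin(dg) * bg)
        return e, g

    def energy_batch(self, phi):
        bt, bg, _, _ = self._bumps(phi)
        return self.B[None, :] * (1.0 - bt - bg)[:, None]


class _PreferenceBlock:
    def __init__(self, coord_index, terms):
        self.j = coord_index
        t0 = terms[0]
        if any((t.sharpness, t.boundary) != (t0.sharpness, t0.boundary) for t in terms):
            raise ValueError("preference switch geometry must be shared across endstates")
        self.lam = t0.sharpness
        self.boundary = t0.boundary
        # signed tilt: +eps deepens gauche, applied as −eps_g·σ_g − eps_t·σ_t
        self.eps_g = np.array([t.eps if t.well == "gauche" else 0.0 for t in terms])
        self.eps_t = np.array([t.eps if t.well == "trans" else 0.0 for t in terms])

    def _sigma_g(self, phi):
        # σ_g ≈ 1 in the gauche basin, 0 in the trans basin
        s = np.sin((np.asarray(phi, float) - self.boundary) * _DEG)
        return 0.5 * (1.0 - np.tanh(self.lam * s)), s

    def energy(self, phi):
        sg, _ = self._sigma_g(phi)
        return -self.eps_g * sg - self.eps_t * (1.0 - sg)

    def gradient(self, phi):
        s = np.sin((phi - self.boundary) * _DEG)
        c = np.cos((phi - self.boundary) * _DEG)
        dsg = -0.5 * self.lam * (1.0 - np.tanh(self.lam * s) ** 2) * c * _DEG
        return (self.eps_t - self.eps_g) * dsg

    def energy_and_gradient(self, phi):
        s = np.sin((phi - self.boundary) * _DEG)
        c = np.cos((phi - self.boundary) * _DEG)
        th = np.tanh(self.lam * s)
        sg = 0.5 * (1.0 - th)
        e = -self.eps_g * sg - self.eps_t * (1.0 - sg)
        dsg = -0.5 * self.lam * (1.0 - th**2) * c * _DEG
        return e, (self.eps_t - self.eps_g) * dsg

    def energy_batch(self, phi):
        sg, _ = self._sigma_g(phi)
        return -self.eps_g[None, :] * sg[:, None] - self.eps_t[None, :] * (1.0 - sg)[:, None]


_BLOCKS = {Harmonic: _HarmonicBlock, TwoWell: _TwoWellBlock, WellPreference: _PreferenceBlock}


class ToySystem:
    """A set of endstates sharing a common coordinate space.

    All endstates must carry the same term layout (same term types on the
    same coordinates, slot by slot) so the system can be evaluated for all
    endstates at once.
    """

    def __init__(self, coordinates, endstates, restraint: FlatBottomRestraint | None = None):
        self.coordinates = tuple(coordinates)
        self.endstates = tuple(endstates)
        self.restraint = restraint
        if len({c.name for c in self.coordinates}) != len(self.coordinates):
            raise ValueError("duplicate coordinate names")
        if not self.endstates:
            raise ValueError("system needs at least one endstate")
        if len({e.id for e in self.endstates}) != len(self.endstates):
            raise ValueError("duplicate endstate ids")
        self._coord_index = {c.name: j for j, c in enumerate(self.coordinates)}
        layout = [(type(t), t.coord) for t in self.endstates[0].terms]
        for e in self.endstates:
            if [(type(t), t.coord) for t in e.terms] != layout:
                raise ValueError("all endstates must share the same term layout")
        for typ, coord in layout:
            if coord not in self._coord_index:
                raise ValueError(f"term references unknown coordinate {coord!r}")
        self._blocks = [
            _BLOCKS[typ](self._coord_index[coord], [e.terms[slot] for e in self.endstates])
            for slot, (typ, coord) in enumerate(layout)
        ]
        if restraint is not None and restraint.coord not in self._coord_index:
            raise ValueError(f"restraint references unknown coordinate {restraint.coord!r}")
        self.depths = np.array([e.depth for e in self.endstates])

    @property
    def endstate_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.endstates)

    @property
    def n_endstates(self) -> int:
        return len(self.endstates)

    def endstate(self, endstate_id: str) -> EndState:
        for e in self.endstates:
            if e.id == endstate_id:
                return e
        raise KeyError(f"unknown endstate {endstate_id!r}")

    def validate_coords(self, x) -> None:
        x = np.asarray(x, float)
        if x.shape != (len(self.coordinates),):
            raise ValueError(
                f"expected {len(self.coordinates)} coordinates, got shape {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("coordinates must be finite")
        for xc, c in zip(x, self.coordinates):
            if c.kind == "linear" and not (c.lo <= xc <= c.hi):
                raise ValueError(
                    f"coordinate {c.name!r}={xc} outside domain [{c.lo}, {c.hi}]"
                )

    def wrap(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, float)
        for j, c in enumerate(self.coordinates):
            out[j] = c.wrap(out[j])
        return out

    def endstate_energies_and_gradients(self, x):
        """(H_i, ∇H_i) for every endstate at a single configuration.

        Returns ``(h, grads)`` with ``h`` shape (N,) and ``grads`` shape
        (N, n_coords). The restraint is *not* included (it belongs to the
        sampled Hamiltonian, not to any endstate).
        """
        h = self.depths.copy()
        grads = np.zeros((len(self.endstates), len(self.coordinates)))
        for b in self._blocks:
            e, g = b.energy_and_gradient(x[b.j])
            h = h + e
            grads[:, b.j] += g
        return h, grads

    def endstate_energies(self, x):
        h = self.depths.copy()
        for b in self._blocks:
            h = h + b.energy(x[b.j])
        return h

    def endstate_energies_batch(self, X):
        """Endstate energies for many configurations: X (n, d) → (n, N)."""
        X = np.asarray(X, float)
        h = np.broadcast_to(self.depths, (X.shape[0], len(self.endstates))).copy()
        for b in self._blocks:
            h += b.energy_batch(X[:, b.j])
        return h

    def restraint_energy_and_gradient(self, x):
        r = self.restraint
        return float(r.energy(x[self._coord_index[r.coord]])), self._restraint_grad_vec(x)

    def _restraint_grad_vec(self, x):
        g = np.zeros(len(self.coordinates))
        j = self._coord_index[self.restraint.coord]
        g[j] = self.restraint.gradient(x[j])
        return g

    def per_coordinate_potential(self, endstate_id: str, coord: str, values):
        """Σ of the endstate's terms on one coordinate, restraint included.

        The endstate depth is excluded (it is coordinate-independent).
        """
        slot_terms = self.endstate(endstate_id).terms
        idx = self.endstate_ids.index(endstate_id)
        values = np.atleast_1d(np.asarray(values, float))
        v = np.zeros_like(values)
        for slot, t in enumerate(slot_terms):
            if t.coord == coord:
                v += self._blocks[slot].energy_batch(values)[:, idx]
        if self.restraint is not None and self.restraint.coord == coord:
            v += self.restraint.energy(values)
        return v

    def minimum_of(self, endstate_id: str) -> np.ndarray:
        """Approximate configuration of the endstate's global minimum."""
        x = np.zeros(len(self.coordinates))
        for j, c in enumerate(self.coordinates):
            grid = np.linspace(c.lo, c.hi, 721)
            v = self.per_coordinate_potential(endstate_id, c.name, grid)
            x[j] = grid[int(np.argmin(v))]
        return x

    def orthogonal_coordinate(self):
        """The periodic coordinate carrying a two-well term, or None."""
        for e_terms in (self.endstates[0].terms,):
            for t in e_terms:
                if isinstance(t, TwoWell):
                    c = self.coordinates[self._coord_index[t.coord]]
                    if c.kind == "periodic":
                        return c, t
        return None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(mapping):
            return {
                k: (float(v) if isinstance(v, (float, np.floating)) else v)
                for k, v in mapping.items()
            }

        def term_dict(t):
            return clean({"type": type(t).__name__, **t.__dict__})

        d = {
            "coordinates": [clean(c.__dict__) for c in self.coordinates],
            "endstates": [
                {"id": e.id, "depth": float(e.depth), "terms": [term_dict(t) for t in e.terms]}
                for e in self.endstates
            ],
        }
        if self.restraint is not None:
            d["restraint"] = clean(self.restraint.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystem":
        term_types = {"Harmonic": Harmonic, "TwoWell": TwoWell, "WellPreference": WellPreference}
        allowed = {"coordinates", "endstates", "restraint"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown system keys: {sorted(unknown)}")
        coords = [Coordinate(**c) for c in d["coordinates"]]
        endstates = []
        for e in d["endstates"]:
            terms = []
            for t in e["terms"]:
                t = dict(t)
                typ = term_types[t.pop("type")]
                terms.append(typ(**t))
            endstates.append(EndState(e["id"], float(e["depth"]), tuple(terms)))
        restraint = None
        if "restraint" in d and d["restraint"] is not None:
            restraint = FlatBottomRestraint(**d["restraint"])
        return cls(coords, endstates, restraint)


@dataclass(frozen=True)
class OracleResult:
    """Exact per-endstate free energies and orthogonal-well populations."""

    ids: tuple[str, ...]
    free_energies: np.ndarray  # G_i = −RT ln Z_i, kJ·mol⁻¹
    populations: dict  # id -> (p_trans, p_gauche), empty if no orthogonal coord

    def delta_g(self, i: str, j: str) -> float:
        """ΔG_ij = G_j − G_i (antisymmetric by construction)."""
        ids = list(self.ids)
        return float(self.free_energies[ids.index(j)] - self.free_energies[ids.index(i)])


def make_t4l_like_toy(
    n_states: int,
    barrier: float = 25.0,
    preference_split: int | None = None,
    seed: int = 0,
    *,
    eps: float = 5.0,
    depths=None,
    k_range: tuple[float, float] = (25.0, 35.0),
    spacing: float = 2.0,
    restrain: bool = True,
) -> ToySystem:
    """Deterministic multi-endstate toy in the style of a cavity-binding series.

    Parameters
    ----------
    n_states : int
        Number of endstates ("ligands"), ≥ 2 for free-energy work (1 is
        allowed for degenerate baselines).
    barrier : float
        Orthogonal two-well barrier height in kJ·mol⁻¹ (≥ 0), measured from
        the unpreferred well bottom.
    preference_split : int
        How many endstates prefer the gauche well (the "bulky" ones: the
        deepest endstates get the gauche preference). Defaults to
        ``n_states // 2``.
    seed : int
        Seed for the endstate depths and binding-well force constants.
    eps : float
        Magnitude of the well preference in kJ·mol⁻¹.
    depths : sequence of float, optional
        Explicit endstate depths (relative binding strengths); overrides
        the seeded draw from U(−3, 3).
    restrain : bool
        Attach a flat-bottom restraint confining the binding coordinate
        (the analogue of weak binding-site restraints). On by default so
        the force-free region above E_max cannot drift arbitrarily far.
    """
    if n_states < 1:
        raise ValueError("n_states must be ≥ 1")
    if preference_split is None:
        preference_split = n_states // 2
    if not (0 <= preference_split <= n_states):
        raise ValueError("preference_split must lie in [0, n_states]")
    if barrier < 0:
        raise ValueError("barrier must be ≥ 0")
    rng = np.random.default_rng(seed)
    ks = rng.uniform(*k_range, size=n_states)
    if depths is None:
        depths = rng.uniform(-3.0, 3.0, size=n_states)
    depths = np.asarray(depths, float)
    if depths.shape != (n_states,):
        raise ValueError("depths must have one entry per endstate")
    centers = (np.arange(n_states) - (n_states - 1) / 2.0) * spacing
    # bulkiest = deepest endstates prefer gauche
    order = np.argsort(depths)  # ascending: deepest first
    gauche_set = set(order[:preference_split].tolist())

    half = centers[-1] - centers[0] if n_states > 1 else 0.0
    x_lo, x_hi = centers[0] - 8.0, centers[-1] + 8.0
    coords = [
        Coordinate("x", "linear", x_lo, x_hi, friction=1.0),
        Coordinate("phi", "periodic", -180.0, 180.0, friction=0.0025),
    ]
    endstates = []
    for i in range(n_states):
        terms = (
            Harmonic("x", float(centers[i]), float(ks[i])),
            TwoWell("phi", float(barrier)),
            WellPreference("phi", float(eps), "gauche" if i in gauche_set else "trans"),
        )
        endstates.append(EndState(f"s{i + 1:02d}", float(depths[i]), terms))
    restraint = None
    if restrain:
        restraint = FlatBottomRestraint("x", float(np.mean(centers)), half / 2.0 + 2.0, 10.0)
    return ToySystem(coords, endstates, restraint)


def _coordinate_partition(system: ToySystem, endstate_id: str, ctx: ThermoContext, coord: Coordinate):
    """ln ∫ exp(−V_c/RT) over one coordinate, by adaptive quadrature."""

    def integrand(v):
        return np.exp(-system.per_coordinate_potential(endstate_id, coord.name, v)[0] / ctx.RT)

    # reference the integrand to its minimum for numerical stability
    grid = np.linspace(coord.lo, coord.hi, 1441)
    vals = system.per_coordinate_potential(endstate_id, coord.name, grid)
    v0 = float(np.min(vals))

    def shifted(v):
        return np.exp(-(system.per_coordinate_potential(endstate_id, coord.name, v)[0] - v0) / ctx.RT)

    z, err = quad(shifted, coord.lo, coord.hi, epsabs=1e-10, epsrel=1e-10, limit=400)
    return math.log(z) - v0 / ctx.RT, err / max(z, 1e-300)


def exact_free_energy(system: ToySystem, endstate_id: str, ctx: ThermoContext) -> float:
    """Exact G_i = −RT·ln ∫ exp(−V_i/RT) dx by per-coordinate quadrature.

    The configuration integral is taken in the coordinates' native units
    (length units for x, degrees for φ); the associated additive constant
    is common to all endstates and cancels in every ΔG. The restraint term
    is included if the system defines one.
    """
    if len(system.coordinates) > 2:
        raise ValueError("quadrature oracle supports at most 2 coordinates")
    ln_z = 0.0
    for c in system.coordinates:
        lz, _ = _coordinate_partition(system, endstate_id, ctx, c)
        ln_z += lz
    return system.endstate(endstate_id).depth - ctx.RT * ln_z


def oracle_free_energies(system: ToySystem, ctx: ThermoContext) -> OracleResult:
    """Exact free energies (and well populations, if applicable) for all endstates."""
    g = np.array([exact_free_energy(system, i, ctx) for i in system.endstate_ids])
    pops = {}
    if system.orthogonal_coordinate() is not None:
        for i in system.endstate_ids:
            pops[i] = exact_orthogonal_populations(system, i, ctx)
    return OracleResult(system.endstate_ids, g, pops)


def basin_boundaries(system: ToySystem, endstate_id: str) -> tuple[float, float]:
    """The two potential maxima separating the trans and gauche basins.

    Returned as (boundary near the short arc, boundary near the long arc),
    in degrees.
    """
    found = system.orthogonal_coordinate()
    if found is None:
        raise ValueError("system has no periodic two-well coordinate")
    c, tw = found

    def v(phi):
        return system.per_coordinate_potential(endstate_id, c.name, c.wrap(phi))

    bounds = []
    for lo, hi in _arcs_between_wells(tw):
        grid = np.linspace(lo, hi, 2001)
        vals = v(grid)
        vmax = float(np.max(vals))
        near = np.flatnonzero(vals >= vmax - 1e-9)
        # flat barrier tops (e.g. zero-barrier systems): take the candidate
        # closest to the geometric arc midpoint
        mid = 0.5 * (lo + hi)
        pick = near[int(np.argmin(np.abs(grid[near] - mid)))]
        if abs(grid[pick] - mid) > 45.0:
            # no genuine inter-well maximum (degenerate, e.g. barrier ≈ 0):
            # fall back to the geometric midpoint between the wells
            bounds.append(mid)
            continue
        if 0 < pick < len(grid) - 1 and near.size == 1:
            res = minimize_scalar(
                lambda p: -v(p)[0],
                bounds=(grid[pick - 1], grid[pick + 1]),
                method="bounded",
                options={"xatol": 1e-8},
            )
            bounds.append(float(res.x))
        else:
            bounds.append(float(grid[pick]))
    return tuple(bounds)


def _arcs_between_wells(tw: TwoWell):
    # arcs between gauche (−60) and trans (180), in unwrapped angles
    wg, wt = tw.well_gauche, tw.well_trans
    return [(wg + 1.0, wt - 1.0), (wt + 1.0, wg + 360.0 - 1.0)]


def exact_orthogonal_populations(
    system: ToySystem, endstate_id: str, ctx: ThermoContext
) -> tuple[float, float]:
    """Exact (p_trans, p_gauche) for one endstate by basin-restricted quadrature.

    The basin split is placed at the potential maxima between the wells,
    so p_trans + p_gauche = 1 by construction.
    """
    found = system.orthogonal_coordinate()
    if found is None:
        raise ValueError("system has no periodic two-well coordinate")
    c, tw = found
    b1, b2 = basin_boundaries(system, endstate_id)  # b1 in (wg, wt), b2 in (wt, wg+360)

    grid = np.linspace(c.lo, c.hi, 1441)
    v0 = float(np.min(system.per_coordinate_potential(endstate_id, c.name, grid)))

    def weight(phi):
        phi = c.wrap(phi)
        return np.exp(-(system.per_coordinate_potential(endstate_id, c.name, phi)[0] - v0) / ctx.RT)

    z_trans, _ = quad(weight, b1, b2, epsabs=1e-12, epsrel=1e-10, limit=400)
    z_gauche, _ = quad(weight, b2, b1 + 360.0, epsabs=1e-12, epsrel=1e-10, limit=400)
    z = z_trans + z_gauche
    return z_trans / z, z_gauche / z


def well_label(phi, boundary: float = 60.0):
    """Geometric trans/gauche basin label(s) for dihedral value(s) in degrees.

    1 = trans basin, 0 = gauche basin; the split is at the inter-well
    midpoints (boundary and boundary ± 180).
    """
    s = np.sin((np.asarray(phi, float) - boundary) * _DEG)
    return (s > 0).astype(int)
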