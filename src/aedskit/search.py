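"""Adaptive search for the AEDS acceleration parameters.

A search run interleaves short simulation segments with parameter
updates. Running statistics are taken over a trailing memory window whose
length grows linearly from ``w_start`` to ``w_end`` samples across the
search, so estimates fluctuate rapidly at first and settle toward the
end:

* **E_max** — the windowed maximum of the reference energy H_R over
  *transition frames*, i.e. frames at which the lowest-energy endstate
  changes: the typical energy of a state crossing.
* **E_min** — the windowed mean, over endstates, of each endstate's
  running minimum of H_i − ΔF_i^R: the level of the envelope's minima.
* **offsets** — windowed perturbation (exponential-averaging) estimates of
  each endstate's free energy relative to the sampled state, gauged so the
  anchor endstate's offset is zero. At their optimum the offsets equal the
  endstates' free-energy differences and the reference state samples all
  endstates roughly equally.

Final reported values are means over the converged tail of the search
after removing value spikes (median-absolute-deviation filter); spikes
arise when a state has not been sampled for a while.

The same offset formula applied to a finished production run
(`update_offsets`) refines offsets that a too-short search got wrong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

from .dynamics import EnergyTrajectory, SimulationConfig, simulate
from .estimators import UnsupportedEndstateWarning
from .hamiltonian import AccelerationParams, OffsetVector
from .thermo import ThermoContext
from .toys import ToySystem

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "search_run",
    "update_offsets",
    "filter_spikes",
    "group_endstates",
    "memory_window",
]


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the adaptive parameter search.

    ``mode`` is "all" (E_max, E_min and offsets all float — the solvent
    stage) or "offsets-only" (E_max/E_min fixed to supplied values — the
    bound stage). ``w_start``/``w_end`` bound the linear memory-window
    schedule, in samples; ``kappa`` is the spike-filter MAD multiplier.
    """

    n_steps: int = 40000
    w_start: int = 1000
    w_end: int = 10000
    mode: str = "all"
    anchor: str | None = None
    kappa: float = 5.0
    update_interval: int = 200
    min_ess: float = 8.0
    max_offset_step: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("all", "offsets-only"):
            raise ValueError("mode must be 'all' or 'offsets-only'")
        if not (0 < self.w_start <= self.w_end):
            raise ValueError("need 0 < w_start ≤ w_end")
        if self.n_steps < self.w_start:
            raise ValueError("search shorter than the initial memory window")
        if self.update_interval < 1:
            raise ValueError("update_interval must be ≥ 1")


@dataclass
class SearchTrace:
    """Per-update parameter estimates: instantaneous and filtered running.

    The ``*_inst`` series are the raw windowed estimates (spikes and all);
    ``e_max``, ``e_min`` and ``offsets`` are the spike-filtered running
    means that actually drive the simulation and whose final entries are
    the reported parameters.
    """

    steps: np.ndarray
    e_max: np.ndarray
    e_min: np.ndarray
    offsets: np.ndarray  # (n_updates, n_endstates)
    e_max_inst: np.ndarray
    e_min_inst: np.ndarray
    offsets_inst: np.ndarray
    ids: tuple[str, ...]
    converged: bool = False

    def offset_se(self, tail_frac: float = 0.5, n_blocks: int = 4) -> np.ndarray:
        """Standard error of the final offsets from the instantaneous tail.

        The trailing ``tail_frac`` of the instantaneous estimates is split
        into ``n_blocks`` blocks; the SE is the standard deviation of the
        block means over √n_blocks (robust to the autocorrelation of
        overlapping memory windows).
        """
        start = int(len(self.steps) * (1.0 - tail_frac))
        tail = self.offsets_inst[start:]
        n = tail.shape[1]
        se = np.empty(n)
        for k in range(n):
            series = tail[:, k]
            series = series[np.isfinite(series)]
            if series.size < n_blocks:
                se[k] = np.nan
                continue
            blocks = np.array_split(series, n_blocks)
            means = [np.mean(filter_spikes(b)) for b in blocks]
            se[k] = np.std(means, ddof=1) / np.sqrt(n_blocks)
        return se


def memory_window(t: int, total: int, w_start: int, w_end: int) -> int:
    """Linearly growing trailing-window length, clamped to [w_start, w_end]."""
    frac = min(max(t / max(total, 1), 0.0), 1.0)
    return int(round(min(max(w_start + (w_end - w_start) * frac, w_start), w_end)))


def filter_spikes(series, kappa: float = 5.0) -> np.ndarray:
    """Drop points farther than κ scaled-MADs from the median.

    The MAD is scaled by 1.4826 (consistent with a normal σ). If every
    point would be removed, the median alone is returned.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    keep = np.abs(x - med) <= kappa * mad
    if not np.any(keep):
        return np.array([med])
    return x[keep]


def _windowed_dg(h, h_star, RT):
    """Perturbation free-energy estimates over a frame block, with support.

    Returns ``(dg, ess)``: the exponential-averaging estimate per endstate
    and its effective sample size (Σu)²/Σu². An endstate whose weight is
    carried by fewer than a handful of frames has a meaninglessly biased
    estimate; callers gate on the ESS.
    """
    a = -(h - h_star[:, None]) / RT
    lse = logsumexp(a, axis=0)
    lse2 = logsumexp(2.0 * a, axis=0)
    with np.errstate(invalid="ignore"):
        ess = np.exp(2.0 * lse - lse2)
    dg = -RT * (lse - np.log(h.shape[0]))
    return dg, ess


def search_run(
    system: ToySystem,
    cfg: SearchConfig,
    sim_cfg: SimulationConfig,
    params: AccelerationParams | None = None,
) -> tuple[AccelerationParams, SearchTrace]:
    """Determine acceleration parameters from an adaptive search simulation.

    In "all" mode the search starts unboosted, turns the boost on as soon
    as both thresholds have been observed, and lets E_max, E_min and the
    offsets float together. In "offsets-only" mode ``params`` must supply
    E_max/E_min (and starting offsets), which are held fixed while the
    offsets float.

    Returns the final parameters (anchor offset exactly 0) and the trace
    of instantaneous estimates.
    """
    ids = system.endstate_ids
    n = len(ids)
    anchor = cfg.anchor or ids[0]
    if anchor not in ids:
        raise ValueError(f"anchor {anchor!r} is not an endstate of the system")
    ai = ids.index(anchor)
    RT = ThermoContext(sim_cfg.temperature).RT

    if cfg.mode == "offsets-only":
        if params is None:
            raise ValueError("offsets-only search requires starting params")
        e_min, e_max = params.e_min, params.e_max
        off = params.offsets.aligned(ids)
        boost_on = True
    else:
        e_min = e_max = np.nan
        off = np.zeros(n) if params is None else params.offsets.aligned(ids)
        boost_on = False

    h_all = np.empty((0, n))
    h_r_all = np.empty(0)
    h_star_all = np.empty(0)
    x = None
    rng = np.random.default_rng(sim_cfg.seed)

    rec_steps = []
    inst_emax, inst_emin, inst_off = [], [], []
    run_emax, run_emin, run_off = [], [], []

    def _running(series, current):
        """Spike-filtered mean of the trailing half of the finite estimates."""
        vals = np.asarray(series, float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return current
        tail = vals[len(vals) // 2 :]
        return float(np.mean(filter_spikes(tail, cfg.kappa)))

    t = 0
    while t < cfg.n_steps:
        seg = min(cfg.update_interval, cfg.n_steps - t)
        seg_params = AccelerationParams(
            e_min if boost_on else -1e9,
            e_max if boost_on else 1e9,
            OffsetVector.from_values(ids, off, anchor),
        )
        mode = "reference-AEDS" if boost_on else "reference-EDS-no-boost"
        seg_cfg = replace(
            sim_cfg,
            n_steps=seg,
            stride=1,
            seed=int(rng.integers(2**31 - 1)),
            initial=None if x is None else tuple(x),
            mode=mode,
        )
        traj = simulate(system, seg_params, seg_cfg)
        x = traj.coords[-1]
        t += seg
        h_all = np.vstack([h_all, traj.h])
        h_r_all = np.concatenate([h_r_all, traj.h_r])
        h_star_all = np.concatenate([h_star_all, traj.h_star])

        w = min(memory_window(t, cfg.n_steps, cfg.w_start, cfg.w_end), len(h_r_all))
        hw = h_all[-w:]
        hrw = h_r_all[-w:]
        hsw = h_star_all[-w:]

        shifted = hw - off
        assign = np.argmin(shifted, axis=1)
        cand_max = cand_min = np.nan
        if cfg.mode == "all":
            if n == 1:
                cand_max, cand_min = float(np.max(hrw)), float(np.min(hrw))
            else:
                crossings = np.flatnonzero(np.diff(assign) != 0) + 1
                cand_max = float(np.max(hrw[crossings])) if crossings.size else np.nan
                # mean of per-endstate minima, over endstates actually
                # visited in the window: a never-visited endstate's windowed
                # minimum reflects distance, not its energy level
                visited = np.unique(assign)
                cand_min = float(np.mean(np.min(shifted[:, visited], axis=0)))
            inst_emax.append(cand_max)
            inst_emin.append(cand_min)
            new_max = _running(inst_emax, e_max)
            new_min = _running(inst_emin, e_min)
            # commit thresholds only while they are consistent; transient
            # assignment flicker near the minima can otherwise drag the
            # crossing maximum below the envelope minimum
            if np.isfinite(new_max) and np.isfinite(new_min) and new_min < new_max:
                e_max, e_min = new_max, new_min
                boost_on = True
        else:
            inst_emax.append(e_max)
            inst_emin.append(e_min)

        dg_rel = np.full(n, np.nan)
        if len(h_r_all) >= cfg.w_start:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                dg, ess = _windowed_dg(hw, hsw, RT)
            supported = np.isfinite(dg) & (ess >= cfg.min_ess)
            if supported[ai]:
                dg_rel = np.where(supported, dg - dg[ai], np.nan)
        inst_off.append(dg_rel)
        target = np.array(
            [_running([row[k] for row in inst_off], off[k]) for k in range(n)]
        )
        # trust region: a single update may not move an offset by more than
        # max_offset_step, so an unsupported, wildly biased estimate cannot
        # tilt the reference state faster than sampling can respond
        step = np.clip(target - off, -cfg.max_offset_step, cfg.max_offset_step)
        off = off + step
        off = off - off[ai]

        rec_steps.append(t)
        run_emax.append(e_max)
        run_emin.append(e_min)
        run_off.append(off.copy())

    if cfg.mode == "all" and n > 1 and not boost_on:
        raise RuntimeError(
            "no transitions between endstates observed during the search; "
            "extend the search run or use a smaller/less separated system"
        )

    trace = SearchTrace(
        steps=np.asarray(rec_steps),
        e_max=np.asarray(run_emax, float),
        e_min=np.asarray(run_emin, float),
        offsets=np.asarray(run_off),
        e_max_inst=np.asarray(inst_emax, float),
        e_min_inst=np.asarray(inst_emin, float),
        offsets_inst=np.asarray(inst_off),
        ids=ids,
    )
    trace.converged = _converged(trace)
    final = AccelerationParams(
        float(e_min), float(e_max), OffsetVector.from_values(ids, off, anchor)
    )
    return final, trace


def _converged(trace: SearchTrace, window_frac: float = 0.2, tol: float = 0.01) -> bool:
    """E_max and E_min drift below ``tol`` (relative) over the trailing fifth."""
    k = max(int(len(trace.steps) * window_frac), 2)
    for series in (trace.e_max, trace.e_min):
        s = series[-k:]
        s = s[np.isfinite(s)]
        if s.size < 2:
            return False
        scale = max(abs(np.mean(s)), 1e-9)
        if (np.max(s) - np.min(s)) / scale > tol:
            return False
    return True


def update_offsets(
    traj: EnergyTrajectory,
    params: AccelerationParams,
    cfg: SearchConfig,
    ctx: ThermoContext,
) -> OffsetVector:
    """Re-estimate offsets from a production trajectory.

    Applies the search-run offset formula to the finished run: windowed
    perturbation estimates ΔG_i(t) over the trailing memory window W(t),
    evaluated every ``cfg.update_interval`` frames, then a spike-filtered
    mean of ΔG_i − ΔG_anchor over the usable tail. Endstates never
    supported by the ensemble keep their previous offset (with a warning).
    """
    ids = traj.ids
    anchor = cfg.anchor or params.offsets.anchor
    ai = ids.index(anchor)
    n_frames = traj.n_frames
    if n_frames < cfg.w_start:
        raise ValueError(
            f"trajectory has {n_frames} frames, fewer than the initial window {cfg.w_start}"
        )
    h_s = traj.h_sampled
    points = range(cfg.w_start, n_frames + 1, cfg.update_interval)
    estimates = []
    for t in points:
        w = min(memory_window(t, n_frames, cfg.w_start, cfg.w_end), t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dg, ess = _windowed_dg(traj.h[t - w : t], h_s[t - w : t], ctx.RT)
        estimates.append(np.where(np.isfinite(dg) & (ess >= cfg.min_ess), dg, np.nan))
    est = np.asarray(estimates)
    rel = est - est[:, [ai]]
    old = params.offsets.aligned(ids)
    new = np.empty(len(ids))
    for k in range(len(ids)):
        series = rel[:, k]
        series = series[np.isfinite(series)]
        if series.size == 0:
            warnings.warn(
                f"endstate {ids[k]!r} unsampled in production run; offset carried over",
                UnsupportedEndstateWarning,
                stacklevel=2,
            )
            new[k] = old[k]
        else:
            new[k] = np.mean(filter_spikes(series, cfg.kappa))
    return OffsetVector.from_values(ids, new, anchor)


def _bhattacharyya(x, y, lo, hi, bins):
    px, edges = np.histogram(x, bins=bins, range=(lo, hi), density=False)
    py, _ = np.histogram(y, bins=bins, range=(lo, hi), density=False)
    px = px / max(px.sum(), 1)
    py = py / max(py.sum(), 1)
    return float(np.sum(np.sqrt(px * py)))


def group_endstates(
    trajs,
    k_groups: int,
    offsets: OffsetVector,
    *,
    common_required: bool = True,
    bins: int = 40,
):
    """Partition endstates into subgroups by energy-distribution overlap.

    For every pair of endstates (a, b) the similarity is the Bhattacharyya
    coefficient between the histograms of H_a and H_b, conditioned on the
    sampled endstate and averaged over sampling states. Average-linkage
    clustering on 1 − similarity yields ``k_groups`` groups; the endstate
    with the highest mean similarity to all others is added to every group
    as the shared common member (so the groups' free energies can later be
    combined on one scale).

    Returns ``(groups, similarity)`` — a list of id lists and the
    symmetric similarity matrix.
    """
    if isinstance(trajs, EnergyTrajectory):
        trajs = [trajs]
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    ids = trajs[0].ids
    n = len(ids)
    if not (1 <= k_groups <= n):
        raise ValueError(f"k_groups must lie in [1, {n}]")
    h = np.vstack([t.h for t in trajs])
    off = offsets.aligned(ids)
    assign = np.argmin(h - off, axis=1)

    sim = np.eye(n)
    lo, hi = float(np.min(h)), float(np.max(h))
    for a in range(n):
        for b in range(a + 1, n):
            vals = []
            for j in range(n):
                mask = assign == j
                if np.count_nonzero(mask) < 10:
                    continue
                vals.append(_bhattacharyya(h[mask, a], h[mask, b], lo, hi, bins))
            s = float(np.mean(vals)) if vals else 0.0
            sim[a, b] = sim[b, a] = s

    if k_groups == n:
        labels = np.arange(n) + 1
    elif k_groups == 1:
        labels = np.ones(n, dtype=int)
    else:
        dist = squareform(1.0 - sim, checks=False)
        z = linkage(dist, method="average")
        labels = fcluster(z, t=k_groups, criterion="maxclust")

    groups = [[ids[k] for k in range(n) if labels[k] == g] for g in sorted(set(labels))]
    if common_required and n > 1:
        mean_sim = (sim.sum(axis=1) - 1.0) / (n - 1)
        common = ids[int(np.argmax(mean_sim))]
        groups = [g if common in g else g + [common] for g in groups]
    return groups, sim
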