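"""Stochastic individual-based simulator on a periodic square lattice.

Two sessile species live on an L x L torus; each site holds at most one
individual.  Dynamics are continuous-time with three event types per
individual of species ``i``:

* birth attempt at rate ``b_i``: a site is drawn uniformly within the
  dispersal radius; if occupied the birth fails silently;
* intrinsic death at rate ``d_i``;
* kill attempt against species ``k`` at rate ``c_{k,i}``: a site is drawn
  uniformly within the competition radius ``Rc_{k,i}``; an individual of
  species ``k`` found there dies, anything else is a silent no-op.

Scheduling uses random sequential updating with rejection: an individual is
drawn uniformly, an event (possibly a no-op) is drawn against the global
maximum per-capita total rate ``Lmax = max_i (b_i + d_i + c_{1,i} + c_{2,i})``,
and simulated time advances by ``1/(N * Lmax)`` per elementary update.  This
reproduces the per-capita event frequencies of an exact event-driven scheme.
A *time step* elapses when on average every individual has been updated once
(N elementary updates at the current N); densities are recorded once per
step.  The hot loop is numba-compiled; :func:`elementary_update` is the
pure-Python reference implementation of a single update used in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .model_params import ModelSpec, RunConfig, validate_run, validate_spec

__all__ = [
    "EMPTY",
    "LatticeState",
    "Trajectory",
    "neighbourhood_offsets",
    "global_range",
    "init_lattice",
    "elementary_update",
    "run_realisation",
    "save_trajectory",
    "save_snapshot",
    "load_snapshot",
]

EMPTY = 0  # occupancy codes: 0 empty, 1 species 1, 2 species 2

TERMINATION_LABELS = {0: "stationary", 1: "extinction_both", 2: "max_generations"}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def neighbourhood_offsets(radius: float) -> np.ndarray:
    """Integer offsets ``(dx, dy)`` with ``0 < dx^2 + dy^2 <= radius^2``.

    The focal site itself is excluded: offspring are placed away from the
    parent and an individual never kills itself.  The same disc is used for
    dispersal targets and kill targets.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rmax = int(math.floor(radius))
    r2 = radius * radius
    offs = [
        (dx, dy)
        for dx in range(-rmax, rmax + 1)
        for dy in range(-rmax, rmax + 1)
        if (dx or dy) and dx * dx + dy * dy <= r2
    ]
    return np.array(offs, dtype=np.int64)


def global_range(L: int) -> float:
    """Smallest radius whose disc covers every off-origin torus site.

    The minimum-image distance on an L-torus reaches ``L/sqrt(2)`` (the
    diagonally opposite site), so a radius of at least that makes dispersal
    and competition spatially uniform — the exact mean-field geometry.
    """
    return float(math.ceil(L / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class LatticeState:
    """Occupancy of every site plus elapsed time and per-species counts."""

    occupancy: np.ndarray  # (L, L) int8, values {0, 1, 2}
    time: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.int8)

    @property
    def lattice_side(self) -> int:
        return self.occupancy.shape[0]

    @property
    def counts(self) -> tuple[int, int]:
        return (int((self.occupancy == 1).sum()), int((self.occupancy == 2).sum()))

    @property
    def densities(self) -> tuple[float, float]:
        n = self.occupancy.size
        c1, c2 = self.counts
        return (c1 / n, c2 / n)

    def copy(self) -> "LatticeState":
        return LatticeState(self.occupancy.copy(), self.time)


@dataclass
class Trajectory:
    """Per-time-step density record of one realisation."""

    times: np.ndarray            # simulated time at each recorded step
    densities: np.ndarray        # (n_steps, 2)
    terminated_by: str           # stationary | extinction_both | max_generations
    seed: int = 0
    event_counts: dict = field(default_factory=dict)  # births/deaths/kills per species

    @property
    def final_densities(self) -> tuple[float, float]:
        return (float(self.densities[-1, 0]), float(self.densities[-1, 1]))


def init_lattice(spec: ModelSpec, seed: int) -> LatticeState:
    """Initial configuration: independent assignment per site (CSR).

    Each site holds species 1 with probability ``rho_1(0)``, species 2 with
    probability ``rho_2(0)``, else stays empty — a homogeneous Poisson
    process conditioned on the lattice.
    """
    validate_spec(spec)
    L = spec.lattice_side
    r1, r2 = spec.initial_density
    u = np.random.default_rng(seed).random((L, L))
    occ = np.zeros((L, L), dtype=np.int8)
    occ[u < r1] = 1
    occ[(u >= r1) & (u < r1 + r2)] = 2
    return LatticeState(occ)


# ---------------------------------------------------------------------------
# reference single-step implementation (pure Python)
# ---------------------------------------------------------------------------

def _lambda_max(spec: ModelSpec) -> float:
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    # per-capita total rate of an individual of species i: b_i + d_i + sum_k c_{k,i}
    return float(np.max(b + d + c.sum(axis=0)))


def elementary_update(state: LatticeState, spec: ModelSpec, rng: np.random.Generator) -> LatticeState:
    """One elementary update, in place; returns ``state``.

    Draws one individual uniformly, selects an event by rejection against
    the global maximum per-capita rate and executes it; advances time by
    ``1/(N * Lmax)``.  Raises if the community is empty.
    """
    occ = state.occupancy
    L = occ.shape[0]
    xs, ys = np.nonzero(occ)
    n = xs.size
    if n == 0:
        raise ValueError("empty community: no individual to update")
    lam = _lambda_max(spec)
    k = int(rng.integers(n))
    x, y = int(xs[k]), int(ys[k])
    s = int(occ[x, y]) - 1  # 0-based species index
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    u = rng.random() * lam
    if u < b[s]:
        offs = neighbourhood_offsets(spec.species[s].dispersal_radius)
        dx, dy = offs[int(rng.integers(len(offs)))]
        tx, ty = (x + dx) % L, (y + dy) % L
        if occ[tx, ty] == EMPTY:
            occ[tx, ty] = s + 1
    elif u < b[s] + d[s]:
        occ[x, y] = EMPTY
    else:
        acc = b[s] + d[s]
        for victim in range(2):
            acc += c[victim, s]
            if u < acc:
                offs = neighbourhood_offsets(spec.competition.radius[victim][s])
                dx, dy = offs[int(rng.integers(len(offs)))]
                tx, ty = (x + dx) % L, (y + dy) % L
                if occ[tx, ty] == victim + 1:
                    occ[tx, ty] = EMPTY
                break
        # else: rejection no-op
    state.time += 1.0 / (n * lam)
    return state


# ---------------------------------------------------------------------------
# compiled realisation loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def _kernel(occ, L, b, d, c, disp_dx, disp_dy, disp_start,
            comp_dx, comp_dy, comp_start, lam, seed,
            stop_window, stop_tol, max_time, max_steps,
            rec_time, rec_d1, rec_d2, events):  # pragma: no cover - compiled
    np.random.seed(seed)
    nsites = L * L
    # individual index: packed coordinate list + reverse lookup grid
    xs = np.empty(nsites, dtype=np.int32)
    ys = np.empty(nsites, dtype=np.int32)
    sp = np.empty(nsites, dtype=np.int8)
    idx = np.full((L, L), -1, dtype=np.int32)
    n = 0
    counts = np.zeros(2, dtype=np.int64)
    for x in range(L):
        for y in range(L):
            s = occ[x, y]
            if s != 0:
                xs[n] = x
                ys[n] = y
                sp[n] = s
                idx[x, y] = n
                counts[s - 1] += 1
                n += 1
    t = 0.0
    sweep = 0.0
    step = 0
    calm = 0  # consecutive steps with sub-tolerance windowed density change
    rec_time[0] = 0.0
    rec_d1[0] = counts[0] / nsites
    rec_d2[0] = counts[1] / nsites
    term = 2  # max_generations unless decided otherwise
    while True:
        if n == 0:
            term = 1
            break
        if t >= max_time or step >= max_steps:
            term = 2
            break
        n0 = n
        k = np.random.randint(n)
        x = xs[k]
        y = ys[k]
        s = sp[k] - 1
        u = np.random.random() * lam
        if u < b[s]:
            lo = disp_start[s]
            hi = disp_start[s + 1]
            m = lo + np.random.randint(hi - lo)
            tx = (x + disp_dx[m]) % L
            ty = (y + disp_dy[m]) % L
            if occ[tx, ty] == 0:
                occ[tx, ty] = s + 1
                xs[n] = tx
                ys[n] = ty
                sp[n] = s + 1
                idx[tx, ty] = n
                counts[s] += 1
                n += 1
                events[s, 0] += 1
        elif u < b[s] + d[s]:
            occ[x, y] = 0
            idx[x, y] = -1
            last = n - 1
            if k != last:
                xs[k] = xs[last]
                ys[k] = ys[last]
                sp[k] = sp[last]
                idx[xs[k], ys[k]] = k
            counts[s] -= 1
            n -= 1
            events[s, 1] += 1
        else:
            acc = b[s] + d[s]
            for victim in range(2):
                acc += c[victim, s]
                if u < acc:
                    p = victim * 2 + s
                    lo = comp_start[p]
                    hi = comp_start[p + 1]
                    m = lo + np.random.randint(hi - lo)
                    tx = (x + comp_dx[m]) % L
                    ty = (y + comp_dy[m]) % L
                    if occ[tx, ty] == victim + 1:
                        occ[tx, ty] = 0
                        kk = idx[tx, ty]
                        idx[tx, ty] = -1
                        last = n - 1
                        if kk != last:
                            xs[kk] = xs[last]
                            ys[kk] = ys[last]
                            sp[kk] = sp[last]
                            idx[xs[kk], ys[kk]] = kk
                        counts[victim] -= 1
                        n -= 1
                        events[s, 2 + victim] += 1
                    break
        t += 1.0 / (n0 * lam)
        sweep += 1.0 / n0
        if sweep >= 1.0:
            sweep -= 1.0
            step += 1
            rec_time[step] = t
            rec_d1[step] = counts[0] / nsites
            rec_d2[step] = counts[1] / nsites
            if step >= stop_window:
                prev = rec_d1[step - stop_window] + rec_d2[step - stop_window]
                cur = rec_d1[step] + rec_d2[step]
                if abs(cur - prev) < stop_tol:
                    # require the calm to persist for a whole window so a
                    # chance zero net change during a transient cannot stop
                    # the run prematurely
                    calm += 1
                    if calm >= stop_window:
                        term = 0
                        break
                else:
                    calm = 0
    return n, t, step, term


def run_realisation(spec: ModelSpec, run: RunConfig) -> tuple[Trajectory, LatticeState]:
    """Simulate one realisation from a fresh CSR initial condition.

    Densities are recorded once per time step.  The run ends when the net
    change in total density over ``run.stop_window`` steps stays below
    ``run.stop_tolerance`` for ``stop_window`` consecutive steps
    (stationary), when both species are extinct, or at the
    ``max_generations`` cap.  Identical ``(spec, run)`` give bit-identical
    output.
    """
    validate_spec(spec)
    validate_run(run)
    state = init_lattice(spec, run.seed)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    lam = _lambda_max(spec)
    if lam <= 0:
        # no events can ever occur; the initial state is stationary
        dens = np.array([state.densities])
        return (
            Trajectory(np.zeros(1), dens, "stationary", seed=run.seed),
            state,
        )

    disp = [neighbourhood_offsets(s.dispersal_radius) for s in spec.species]
    comp = [
        neighbourhood_offsets(spec.competition.radius[v][a])
        for v in range(2)
        for a in range(2)
    ]
    disp_start = np.array([0, len(disp[0]), len(disp[0]) + len(disp[1])], dtype=np.int64)
    disp_dx = np.concatenate([o[:, 0] for o in disp])
    disp_dy = np.concatenate([o[:, 1] for o in disp])
    comp_start = np.zeros(5, dtype=np.int64)
    comp_start[1:] = np.cumsum([len(o) for o in comp])
    comp_dx = np.concatenate([o[:, 0] for o in comp])
    comp_dy = np.concatenate([o[:, 1] for o in comp])

    # generation = simulated time x smallest positive birth rate; if no
    # species reproduces, a generation is a unit of simulated time
    b_pos = b[b > 0]
    b_min = float(b_pos.min()) if b_pos.size else 1.0
    max_time = run.max_generations / b_min
    # steps are ~1/lam time units apart; generous cap on the record length
    max_steps = int(math.ceil(max_time * lam)) + 2

    rec_time = np.zeros(max_steps + 1)
    rec_d1 = np.zeros(max_steps + 1)
    rec_d2 = np.zeros(max_steps + 1)
    events = np.zeros((2, 4), dtype=np.int64)  # per species: birth, death, kill1, kill2

    occ = state.occupancy
    if int((occ != EMPTY).sum()) == 0:
        dens = np.array([state.densities])
        return (
            Trajectory(np.zeros(1), dens, "extinction_both", seed=run.seed),
            state,
        )

    n, t, step, term = _kernel(
        occ, spec.lattice_side, b, d, c,
        disp_dx, disp_dy, disp_start, comp_dx, comp_dy, comp_start,
        lam, int(run.seed) & 0x7FFFFFFF,
        int(run.stop_window), float(run.stop_tolerance),
        float(max_time), max_steps,
        rec_time, rec_d1, rec_d2, events,
    )
    state.time = t
    # a terminal partial step still deserves a record if something happened
    if term == 1 and (rec_d1[step] > 0 or rec_d2[step] > 0):
        step += 1
        rec_time[step] = t
        rec_d1[step] = 0.0
        rec_d2[step] = 0.0
    traj = Trajectory(
        times=rec_time[: step + 1].copy(),
        densities=np.column_stack([rec_d1[: step + 1], rec_d2[: step + 1]]),
        terminated_by=TERMINATION_LABELS[int(term)],
        seed=run.seed,
        event_counts={
            "births": (int(events[0, 0]), int(events[1, 0])),
            "deaths": (int(events[0, 1]), int(events[1, 1])),
            "kills_of_sp1": (int(events[0, 2]), int(events[1, 2])),
            "kills_of_sp2": (int(events[0, 3]), int(events[1, 3])),
        },
    )
    return traj, state


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "time_step": np.arange(len(traj.times)),
            "time": traj.times,
            "density_sp1": traj.densities[:, 0],
            "density_sp2": traj.densities[:, 1],
        }
    ).to_csv(path, index=False)


def save_snapshot(state: LatticeState, path) -> None:
    """Write occupied sites as CSV columns x, y, species (1 or 2)."""
    xs, ys = np.nonzero(state.occupancy)
    pd.DataFrame(
        {"x": xs, "y": ys, "species": state.occupancy[xs, ys].astype(int)}
    ).to_csv(path, index=False)


def load_snapshot(path, lattice_side: int) -> LatticeState:
    df = pd.read_csv(path)
    occ = np.zeros((lattice_side, lattice_side), dtype=np.int8)
    occ[df["x"].to_numpy(int), df["y"].to_numpy(int)] = df["species"].to_numpy(int)
    return LatticeState(occ)
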