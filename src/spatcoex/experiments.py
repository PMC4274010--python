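"""Ensembles, outcome classification, phase-diagram sweeps and fixtures.

Finite lattices fluctuate, so every reported quantity is an ensemble
average over independent realisations; an ensemble of 20 runs on the
default 150 x 150 lattice has the fluctuations of a single run on a
20-fold larger lattice of 450,000 sites.  Per-realisation seeds are derived
from one base seed through a counter-based scheme
(``numpy.random.SeedSequence(base_seed, point_index, realisation_index)``),
so any single grid point of a sweep can be re-run in isolation and results
do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice_sim import (
    LatticeState,
    Trajectory,
    global_range,
    init_lattice,
    run_realisation,
)
from .meanfield import mf_phase_boundary
from .model_params import ModelSpec, RunConfig, default_spec
from .spatstats import PcfCurve, PointPattern, patterns_from_state

__all__ = [
    "EnsembleResult",
    "PhaseDiagram",
    "derive_seed",
    "run_ensemble",
    "classify_outcome",
    "sweep_phase_diagram",
    "transect",
    "make_fixture",
    "full_scale_manifest",
]


def derive_seed(base_seed: int, *counters: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and counters."""
    state = np.random.SeedSequence([base_seed, *counters]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


@dataclass
class EnsembleResult:
    spec: ModelSpec
    n_realisations: int
    final_densities: np.ndarray       # (n, 2)
    seeds: list[int]
    trajectories: list[Trajectory] = field(default_factory=list)
    states: list[LatticeState] = field(default_factory=list)

    @property
    def mean_densities(self) -> np.ndarray:
        return self.final_densities.mean(axis=0)

    @property
    def stderr_densities(self) -> np.ndarray:
        n = self.n_realisations
        if n == 1:
            return np.zeros(2)
        return self.final_densities.std(axis=0, ddof=1) / math.sqrt(n)


@dataclass
class PhaseDiagram:
    axis_x: str
    axis_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    table: pd.DataFrame               # param_x, param_y, outcome, rho1, rho2, se1, se2
    mf_overlay: pd.DataFrame          # mean-field classification on the same grid


def run_ensemble(
    spec: ModelSpec,
    n: int,
    base_seed: int,
    run: RunConfig | None = None,
    keep_states: bool = False,
    keep_trajectories: bool = False,
    point_index: int = 0,
) -> EnsembleResult:
    """``n`` independent realisations with seeds derived from ``base_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    run = run or RunConfig()
    seeds = [derive_seed(base_seed, point_index, k) for k in range(n)]
    if len(set(seeds)) != n:  # astronomically unlikely, but the contract says distinct
        raise RuntimeError("seed collision in ensemble")
    finals = np.empty((n, 2))
    trajs, states = [], []
    for k, seed in enumerate(seeds):
        traj, state = run_realisation(spec, RunConfig(
            seed=seed,
            stop_window=run.stop_window,
            stop_tolerance=run.stop_tolerance,
            max_generations=run.max_generations,
        ))
        finals[k] = traj.final_densities
        if keep_trajectories:
            trajs.append(traj)
        if keep_states:
            states.append(state)
    return EnsembleResult(spec, n, finals, seeds, trajs, states)


def classify_outcome(ensemble: EnsembleResult, extinct_threshold: float | None = None) -> str:
    """Persistence rule on ensemble-mean stationary densities.

    A species persists iff its mean stationary density exceeds the
    threshold (default one individual per lattice, 1/L^2).
    """
    if extinct_threshold is None:
        extinct_threshold = 1.0 / ensemble.spec.n_sites()
    m = ensemble.mean_densities
    alive = m > extinct_threshold
    if alive.all():
        return "coexistence"
    if alive[0]:
        return "sp1_only"
    if alive[1]:
        return "sp2_only"
    return "both_extinct"


def sweep_phase_diagram(
    spec: ModelSpec,
    axis_x: str = "c12",
    axis_y: str = "d2",
    grid_x=None,
    grid_y=None,
    n_realisations: int = 20,
    base_seed: int = 0,
    run: RunConfig | None = None,
    extinct_threshold: float | None = None,
) -> PhaseDiagram:
    """Ensemble + outcome classification over a 2-parameter grid.

    Stores per-point densities and standard errors so density-vs-parameter
    transects can be read off, and attaches the mean-field classification
    of the same grid as an overlay.
    """
    grid_x = np.atleast_1d(np.asarray(grid_x, dtype=float))
    grid_y = np.atleast_1d(np.asarray(grid_y, dtype=float))
    if grid_x.size == 0 or grid_y.size == 0:
        raise ValueError("empty axis range")
    rows = []
    point = 0
    for vy in grid_y:
        for vx in grid_x:
            s = spec.with_param(axis_x, float(vx)).with_param(axis_y, float(vy))
            ens = run_ensemble(s, n_realisations, base_seed, run=run, point_index=point)
            m, se = ens.mean_densities, ens.stderr_densities
            rows.append(
                {
                    "param_x": float(vx),
                    "param_y": float(vy),
                    "outcome": classify_outcome(ens, extinct_threshold),
                    "rho1": m[0],
                    "rho2": m[1],
                    "se1": se[0],
                    "se2": se[1],
                }
            )
            point += 1
    overlay = mf_phase_boundary(spec, axis_x, axis_y, grid_x, grid_y)
    return PhaseDiagram(axis_x, axis_y, grid_x, grid_y, pd.DataFrame(rows), overlay)


def transect(diagram: PhaseDiagram, axis: str, fixed_value: float) -> pd.DataFrame:
    """Densities along one grid line (axis = the *varying* parameter name)."""
    t = diagram.table
    if axis == diagram.axis_x:
        sel = t[np.isclose(t["param_y"], fixed_value)].sort_values("param_x")
    elif axis == diagram.axis_y:
        sel = t[np.isclose(t["param_x"], fixed_value)].sort_values("param_y")
    else:
        raise ValueError(f"{axis!r} is not an axis of this diagram")
    return sel.reset_index(drop=True)


def full_scale_manifest(step: float = 0.01, n_realisations: int = 20) -> dict:
    """The full-resolution composite-diagram sweep: grid axes and run count.

    c_{1,2} from 0.05 to 0.40 and d_2 from 0.02 to 0.40 in 0.01 increments
    (36 x 39 = 1,404 parameter combinations), 20 realisations each —
    28,080 simulations per composite diagram.  Intended for cluster-scale
    reproduction, not the test suite.
    """
    grid_x = np.round(np.arange(0.05, 0.40 + step / 2, step), 10)
    grid_y = np.round(np.arange(0.02, 0.40 + step / 2, step), 10)
    return {
        "axis_x": "c12",
        "axis_y": "d2",
        "grid_x": grid_x,
        "grid_y": grid_y,
        "n_realisations": n_realisations,
        "run_count": int(grid_x.size * grid_y.size * n_realisations),
    }


# ---------------------------------------------------------------------------
# deterministic fixtures shared across the test suite
# ---------------------------------------------------------------------------

_FIXTURES = (
    "full-lattice",
    "two-cluster",
    "csr",
    "segregation-contrast",
    "heteromyopia-contrast",
    "triadic-contrast",
)


def _synthetic_pcf(edges: np.ndarray, fn, pair) -> PcfCurve:
    """Synthetic PCF curve from a smooth g(r) shape (classifier fixtures)."""
    mids = 0.5 * (edges[:-1] + edges[1:])
    return PcfCurve(edges, np.maximum(fn(mids), 0.0), pair, (0, 0))


def make_fixture(name: str, seed: int = 0, lattice_side: int = 20):
    """Deterministic point patterns / PCF sets used throughout the tests.

    * ``full-lattice``: every site of an L x L lattice occupied by species 1
      (g identically 1).
    * ``two-cluster``: two tight 3x3 blocks of species 1 at opposite corners
      of an L=20 lattice (aggregated at short r, segregated at intermediate).
    * ``csr``: a complete-spatial-randomness pattern of species 1 at density
      0.2 (seeded).
    * ``*-contrast``: synthetic (constructed, not simulated) baseline and
      focal PCF-curve sets plus densities exhibiting the canonical contrast
      of each coexistence mechanism; returns ``(baseline, focal, densities)``.
    """
    if name == "full-lattice":
        xy = np.indices((lattice_side, lattice_side)).reshape(2, -1).T
        return PointPattern(xy, 1, lattice_side)
    if name == "two-cluster":
        L = 20
        block = np.indices((3, 3)).reshape(2, -1).T
        pts = np.vstack([block + [2, 2], block + [12, 12]])
        return PointPattern(pts, 1, L)
    if name == "csr":
        L = max(lattice_side, 50)
        spec = default_spec().replace(lattice_side=L, initial_density=(0.2, 0.0))
        state = init_lattice(spec, seed)
        return patterns_from_state(state)[1]
    if name in ("segregation-contrast", "heteromyopia-contrast", "triadic-contrast"):
        edges = np.arange(0.0, 13.0)
        flat = lambda r: np.ones_like(r)
        if name == "segregation-contrast":
            # near-equivalent species: both clustered, mutually exclusive
            baseline = {
                (1, 1): _synthetic_pcf(edges, flat, (1, 1)),
                (2, 2): _synthetic_pcf(edges, flat, (2, 2)),
                (1, 2): _synthetic_pcf(edges, flat, (1, 2)),
            }
            bump = lambda r: 1.0 + 1.5 * np.exp(-r / 2.0)
            dip = lambda r: 1.0 - 0.6 * np.exp(-r / 2.5)
            focal = {
                (1, 1): _synthetic_pcf(edges, bump, (1, 1)),
                (2, 2): _synthetic_pcf(edges, bump, (2, 2)),
                (1, 2): _synthetic_pcf(edges, dip, (1, 2)),
            }
            dens = (0.22, 0.18)
        elif name == "heteromyopia-contrast":
            # dominant sp1 clusters shrink; rare sp2 stays tightly aggregated
            wide = lambda r: np.where(r < 6.0, 2.2, 0.85) * 1.0
            narrow = lambda r: np.where(r < 2.0, 2.2, 0.85) * 1.0
            tight = lambda r: 1.0 + 2.0 * np.exp(-r / 1.5)
            dip = lambda r: 1.0 - 0.5 * np.exp(-r / 3.0)
            baseline = {
                (1, 1): _synthetic_pcf(edges, wide, (1, 1)),
                (2, 2): _synthetic_pcf(edges, tight, (2, 2)),
                (1, 2): _synthetic_pcf(edges, dip, (1, 2)),
            }
            focal = {
                (1, 1): _synthetic_pcf(edges, narrow, (1, 1)),
                (2, 2): _synthetic_pcf(edges, tight, (2, 2)),
                (1, 2): _synthetic_pcf(edges, dip, (1, 2)),
            }
            dens = (0.30, 0.06)
        else:
            # rare sp2's conspecific clustering flattens toward uniform
            peaked = lambda r: 1.0 + 2.5 * np.exp(-r / 2.0)
            flatter = lambda r: 1.0 + 0.4 * np.exp(-r / 2.0)
            dom = lambda r: 1.0 + 1.2 * np.exp(-r / 2.0)
            dip = lambda r: 1.0 - 0.3 * np.exp(-r / 3.0)
            baseline = {
                (1, 1): _synthetic_pcf(edges, dom, (1, 1)),
                (2, 2): _synthetic_pcf(edges, peaked, (2, 2)),
                (1, 2): _synthetic_pcf(edges, dip, (1, 2)),
            }
            focal = {
                (1, 1): _synthetic_pcf(edges, dom, (1, 1)),
                (2, 2): _synthetic_pcf(edges, flatter, (2, 2)),
                (1, 2): _synthetic_pcf(edges, dip, (1, 2)),
            }
            dens = (0.32, 0.05)
        return baseline, focal, dens
    raise ValueError(f"unknown fixture name: {name!r}; known: {_FIXTURES}")


def longrange_spec(spec: ModelSpec) -> ModelSpec:
    """Copy of ``spec`` with every radius set to the global (mean-field) range."""
    R = global_range(spec.lattice_side)
    s = spec
    for name in ("Rb1", "Rb2", "Rc11", "Rc12", "Rc21", "Rc22"):
        s = s.with_param(name, R)
    return s
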