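"""Mean-field (Lotka-Volterra) analysis of the two-species model.

If every individual experienced the community's average density, the
densities would follow

    drho_i/dt = b_i rho_i (1 - rho_1 - rho_2) - d_i rho_i
                - sum_j c_{i,j} rho_i rho_j

— logistic birth crowding by *total* density (a birth fails when the drawn
site is occupied by anyone) plus active competition kills at rate
``c_{i,j}`` per (victim i, actor j) pair density.  The spatial extension
weights each pairwise density product by a neighbourhood factor g measured
from the point pattern (see :mod:`spatcoex.spatstats`); with all g = 1 the
two coincide.

Stability of the interior fixed point reduces to the condition

    (b_1 + c_{1,1})(b_2 + c_{2,2}) > (b_1 + c_{1,2})(b_2 + c_{2,1})

— the classic intra-must-exceed-inter rule generalised to account for the
birth-rate reduction by overall density.  Equality means the species are
ecologically equivalent and dynamics reduce to drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_params import ModelSpec, validate_spec

__all__ = [
    "MeanFieldResult",
    "mf_rhs",
    "spatial_mf_rhs",
    "mf_fixed_points",
    "mf_jacobian",
    "mf_classify",
    "mf_integrate",
    "mf_phase_boundary",
]

_DRIFT_TOL = 1e-12
_CLASSES = (
    "exclusion_sp1_wins",
    "exclusion_sp2_wins",
    "stable_coexistence",
    "founder_control",
    "ecological_drift",
    "both_extinct",
)


@dataclass
class MeanFieldResult:
    fixed_points: list[tuple[float, float]]
    interior_stable: bool
    classification: str
    eigenvalues: list[np.ndarray]  # Jacobian eigenvalues per fixed point

    @property
    def stable_points(self) -> list[tuple[float, float]]:
        return [
            fp
            for fp, ev in zip(self.fixed_points, self.eigenvalues)
            if np.all(np.real(ev) < 0)
        ]


def mf_rhs(densities, spec: ModelSpec) -> np.ndarray:
    """Time derivatives of the mean densities under the mean-field model."""
    return spatial_mf_rhs(densities, np.ones((2, 2)), np.ones((2, 2)), spec)


def spatial_mf_rhs(densities, g_birth, g_comp, spec: ModelSpec) -> np.ndarray:
    """Spatially-weighted Lotka-Volterra right-hand side.

    ``g_birth[i, j]`` weights the crowding of species j felt by species i
    at its dispersal radius; ``g_comp[i, j]`` weights the density of killer
    species j around victim species i at the competition radius Rc_{i,j}.
    All g = 1 reproduces :func:`mf_rhs` exactly.
    """
    rho = np.asarray(densities, dtype=float)
    g_birth = np.asarray(g_birth, dtype=float)
    g_comp = np.asarray(g_comp, dtype=float)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    crowd = g_birth @ rho           # perceived occupied fraction at birth
    kill = (c * g_comp) @ rho       # per-capita kill pressure on each victim
    return rho * (b * (1.0 - crowd) - d - kill)


def mf_jacobian(densities, spec: ModelSpec) -> np.ndarray:
    """Analytic Jacobian of :func:`mf_rhs`."""
    rho = np.asarray(densities, dtype=float)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    per_cap = b * (1.0 - rho.sum()) - d - c @ rho
    J = np.diag(per_cap) + rho[:, None] * (-b[:, None] - c)
    return J


def mf_fixed_points(spec: ModelSpec) -> list[tuple[float, float]]:
    """All non-negative stationary points, in closed form.

    Always contains (0, 0); each viable boundary point
    ``rho_i* = (b_i - d_i)/(b_i + c_{i,i})``; and the interior solution of
    the 2x2 linear system when it lies strictly inside the simplex.  A
    singular system (ecologically equivalent species) yields a line of
    fixed points and is reported by :func:`mf_classify` as drift.
    """
    validate_spec(spec)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    for i in range(2):
        if b[i] > d[i]:
            r = (b[i] - d[i]) / (b[i] + c[i, i])
            pts.append((r, 0.0) if i == 0 else (0.0, r))
    A = b[:, None] + c          # A[i, j] rho_j = b_i - d_i at the interior point
    rhs = b - d
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) > _DRIFT_TOL:
        rho = np.linalg.solve(A, rhs)
        if rho[0] > 0 and rho[1] > 0 and rho.sum() <= 1:
            pts.append((float(rho[0]), float(rho[1])))
    return pts


def _is_interior(fp) -> bool:
    return fp[0] > 0 and fp[1] > 0


def mf_classify(spec: ModelSpec) -> MeanFieldResult:
    """Outcome of competition under the mean-field model.

    The intra-competition product ``(b_1+c_11)(b_2+c_22)`` against the
    inter-competition product ``(b_1+c_12)(b_2+c_21)`` decides interior
    stability; positivity of the interior point and of the boundary points
    decides which classes are reachable.  Every returned eigenvalue set is
    computed from the analytic Jacobian.
    """
    validate_spec(spec)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    pts = mf_fixed_points(spec)
    eigs = [np.linalg.eigvals(mf_jacobian(fp, spec)) for fp in pts]
    interior = [fp for fp in pts if _is_interior(fp)]
    interior_stable = False
    viable = [b[i] > d[i] for i in range(2)]

    # intra - inter product gap is exactly the determinant of the interior system
    intra = (b[0] + c[0, 0]) * (b[1] + c[1, 1])
    inter = (b[0] + c[0, 1]) * (b[1] + c[1, 0])
    A = b[:, None] + c
    rhs = b - d
    singular = abs(intra - inter) <= 1e-9 * max(intra, inter)
    # with a singular system, drift needs the two zero-growth lines to coincide
    consistent = abs(A[0, 0] * rhs[1] - A[1, 0] * rhs[0]) <= 1e-9 * float(np.abs(A).max())

    if not viable[0] and not viable[1]:
        cls = "both_extinct"
    elif viable[0] and not viable[1]:
        cls = "exclusion_sp1_wins"
    elif viable[1] and not viable[0]:
        cls = "exclusion_sp2_wins"
    elif singular and consistent:
        cls = "ecological_drift"
    elif interior:
        ev = eigs[pts.index(interior[0])]
        interior_stable = bool(np.all(np.real(ev) < 0))
        cls = "stable_coexistence" if interior_stable else "founder_control"
    else:
        # no interior point: the winner is the species whose boundary
        # point resists invasion by the other
        inv2 = b[1] * (1.0 - _boundary(spec, 0)) - d[1] - c[1, 0] * _boundary(spec, 0)
        cls = "exclusion_sp1_wins" if inv2 < 0 else "exclusion_sp2_wins"
    return MeanFieldResult(pts, interior_stable, cls, eigs)


def _boundary(spec: ModelSpec, i: int) -> float:
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    return (b[i] - d[i]) / (b[i] + c[i, i])


def mf_integrate(spec: ModelSpec, rho0, t_end: float = 500.0, n_eval: int = 201):
    """Numerically integrate the mean-field ODE (oracle for classification)."""
    sol = solve_ivp(
        lambda _, y: mf_rhs(y, spec),
        (0.0, t_end),
        np.asarray(rho0, dtype=float),
        t_eval=np.linspace(0.0, t_end, n_eval),
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.t, sol.y.T


def mf_phase_boundary(spec: ModelSpec, axis_x: str, axis_y: str, grid_x, grid_y) -> pd.DataFrame:
    """Classify every grid point of a two-parameter sweep.

    Returns a DataFrame with columns param_x, param_y, class, rho1_star,
    rho2_star (the stable point, or the interior point for founder control
    taken as NaN).  Boundary polylines are where ``class`` changes between
    neighbouring grid cells; see :func:`boundary_segments`.
    """
    rows = []
    for vy in np.atleast_1d(grid_y):
        for vx in np.atleast_1d(grid_x):
            s = spec.with_param(axis_x, float(vx)).with_param(axis_y, float(vy))
            res = mf_classify(s)
            stable = res.stable_points
            if res.classification == "stable_coexistence":
                pt = [fp for fp in res.fixed_points if _is_interior(fp)][0]
            elif stable:
                pt = max(stable, key=lambda fp: fp[0] + fp[1])
            else:
                pt = (np.nan, np.nan)
            rows.append(
                {
                    "param_x": float(vx),
                    "param_y": float(vy),
                    "class": res.classification,
                    "rho1_star": pt[0],
                    "rho2_star": pt[1],
                }
            )
    return pd.DataFrame(rows)


def boundary_segments(grid: pd.DataFrame) -> pd.DataFrame:
    """Midpoint segments between horizontally/vertically adjacent cells whose
    classification differs (a crude polyline of the phase boundary)."""
    xs = np.sort(grid["param_x"].unique())
    ys = np.sort(grid["param_y"].unique())
    cls = grid.pivot(index="param_y", columns="param_x", values="class")
    segs = []
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            if ix + 1 < len(xs) and cls.loc[y, xs[ix + 1]] != cls.loc[y, x]:
                segs.append({"x": 0.5 * (x + xs[ix + 1]), "y": y, "orientation": "v"})
            if iy + 1 < len(ys) and cls.loc[ys[iy + 1], x] != cls.loc[y, x]:
                segs.append({"x": x, "y": 0.5 * (y + ys[iy + 1]), "orientation": "h"})
    return pd.DataFrame(segs, columns=["x", "y", "orientation"])
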