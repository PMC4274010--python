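"""Ecological pressure and coexistence-mechanism diagnostics.

Ecological pressure P_i is the net demographic force on species i, defined
per capita so that drho_i/dt = -rho_i P_i: positive pressure means the
density is falling, and at a stationary state both pressures vanish.  From
the spatial mean-field model,

    P_i = d_i + sum_j c_{i,j} g_comp(i,j) rho_j
          - b_i (1 - sum_j g_birth(i,j) rho_j)

with the neighbourhood factors g measured from the point pattern at the
dispersal radius (birth crowding) and the competition radii (kill terms).
Pressure can also be inferred from a density time series alone as
P_i(t) = -(drho_i/dt)/rho_i, which is how it would be estimated for a
natural community.

Because the g factors are radius-dependent state variables, changing an
interaction radius changes pressure immediately (first order): shrinking
the intra-specific competition radius of an aggregated species raises its
own pressure; shrinking an inter-specific radius against a segregated
competitor lowers the pressure on the victim.  The PCF-contrast classifier
at the bottom turns those signatures into a mechanism call
(spatial segregation / heteromyopia / triadic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice_sim import LatticeState, Trajectory
from .model_params import ModelSpec
from .spatstats import PcfCurve, neighbourhood_factor, patterns_from_state

__all__ = [
    "PressureReport",
    "MechanismCall",
    "measure_g_factors",
    "pressure_formula",
    "pressure_from_state",
    "pressure_from_series",
    "delta_pressure_first_order",
    "classify_mechanism",
]


@dataclass
class PressureReport:
    pressures: tuple[float, float]          # NaN for an extinct species
    source: str                             # "from_state" | "from_series"
    g_birth: np.ndarray | None = None
    g_comp: np.ndarray | None = None
    time: float = np.nan


@dataclass
class MechanismCall:
    label: str                              # spatial_segregation | heteromyopia | triadic | none
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pressure from a lattice snapshot
# ---------------------------------------------------------------------------

def measure_g_factors(state: LatticeState, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood factors at the model's own radii.

    ``g_birth[i, j]``: density of species j around species i at the
    dispersal radius Rb_i.  ``g_comp[i, j]``: density of killer species j
    around victim species i at Rc_{i,j}.  Entries involving an extinct
    species are NaN.
    """
    pats = patterns_from_state(state)
    radii = spec.competition.radius_array()
    g_birth = np.full((2, 2), np.nan)
    g_comp = np.full((2, 2), np.nan)
    for i in range(2):
        if pats[i + 1].n == 0:
            continue
        for j in range(2):
            if pats[j + 1].n == 0:
                continue
            g_birth[i, j] = neighbourhood_factor(
                pats[i + 1], pats[j + 1], spec.species[i].dispersal_radius
            )
            g_comp[i, j] = neighbourhood_factor(
                pats[i + 1], pats[j + 1], radii[i, j]
            )
    return g_birth, g_comp


def pressure_formula(rho, g_birth, g_comp, spec: ModelSpec) -> np.ndarray:
    """Per-capita ecological pressure given densities and g factors.

    Single point of truth for the formula: -rho_i * P_i reproduces
    :func:`spatcoex.meanfield.spatial_mf_rhs` exactly.
    """
    rho = np.asarray(rho, dtype=float)
    g_birth = np.asarray(g_birth, dtype=float)
    g_comp = np.asarray(g_comp, dtype=float)
    b, d = spec.birth_rates(), spec.death_rates()
    c = spec.competition.rate_array()
    return d + (c * g_comp) @ rho - b * (1.0 - g_birth @ rho)


def pressure_from_state(state: LatticeState, spec: ModelSpec) -> PressureReport:
    """Pressure on each species measured from a snapshot.

    g factors are measured from the pattern; an extinct species has
    undefined (NaN) pressure.  Cross factors against an extinct partner
    contribute nothing (the partner density is zero).
    """
    rho = np.array(state.densities)
    g_birth, g_comp = measure_g_factors(state, spec)
    # a zero-density partner contributes 0 regardless of its (undefined) g
    gb = np.where(np.isnan(g_birth) & (rho[None, :] == 0), 0.0, g_birth)
    gc = np.where(np.isnan(g_comp) & (rho[None, :] == 0), 0.0, g_comp)
    p = pressure_formula(rho, gb, gc, spec)
    p = np.where(rho > 0, p, np.nan)
    return PressureReport(
        pressures=(float(p[0]), float(p[1])),
        source="from_state",
        g_birth=g_birth,
        g_comp=g_comp,
        time=state.time,
    )


# ---------------------------------------------------------------------------
# pressure from a density time series
# ---------------------------------------------------------------------------

def pressure_from_series(trajectory: Trajectory, window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Per-species pressure series P_i(t) = -(drho_i/dt)/rho_i.

    Centred finite differences on the recorded steps, then a moving average
    over ``window`` points.  Returns ``(times, pressures)`` where pressures
    has shape (n, 2); requires positive densities throughout.
    """
    t = np.asarray(trajectory.times, dtype=float)
    rho = np.asarray(trajectory.densities, dtype=float)
    if len(t) < window + 1:
        raise ValueError("trajectory shorter than the smoothing window")
    if np.any(rho <= 0):
        raise ValueError("zero density inside the series; pressure undefined")
    drho = np.gradient(rho, t, axis=0)  # centred differences, one-sided at ends
    p = -drho / rho
    if window > 1:
        kern = np.ones(window) / window
        p = np.column_stack([np.convolve(p[:, k], kern, mode="same") for k in range(2)])
    return t, p


def delta_pressure_first_order(
    spec: ModelSpec, state: LatticeState, changed: str, new_value: float
) -> np.ndarray:
    """Predicted immediate pressure change when one radius is altered.

    Only the g factors tied to ``changed`` (one of Rb1, Rb2, Rc11, Rc12,
    Rc21, Rc22) are re-measured at the new radius; densities and every
    other factor keep their current values, so the result is the first-order
    (instantaneous, pattern-frozen) response.
    """
    if changed not in ("Rb1", "Rb2", "Rc11", "Rc12", "Rc21", "Rc22"):
        raise ValueError(f"unknown radius name: {changed!r}")
    rho = np.array(state.densities)
    g_birth, g_comp = measure_g_factors(state, spec)
    gb = np.where(np.isnan(g_birth) & (rho[None, :] == 0), 0.0, g_birth)
    gc = np.where(np.isnan(g_comp) & (rho[None, :] == 0), 0.0, g_comp)
    base = pressure_formula(rho, gb, gc, spec)

    pats = patterns_from_state(state)
    gb2, gc2 = gb.copy(), gc.copy()
    if changed.startswith("Rb"):
        i = int(changed[-1]) - 1
        for j in range(2):
            if pats[i + 1].n and pats[j + 1].n:
                gb2[i, j] = neighbourhood_factor(pats[i + 1], pats[j + 1], new_value)
    else:
        i, j = int(changed[-2]) - 1, int(changed[-1]) - 1
        if pats[i + 1].n and pats[j + 1].n:
            gc2[i, j] = neighbourhood_factor(pats[i + 1], pats[j + 1], new_value)
    new = pressure_formula(rho, gb2, gc2, spec)
    return new - base


# ---------------------------------------------------------------------------
# mechanism classification from PCF contrasts
# ---------------------------------------------------------------------------

_AGG = 1.1          # g above this at short range counts as aggregated
_SEG = 0.9          # cross g below this counts as segregated
_EXTENT_DROP = 0.25  # fractional cluster-radius reduction for heteromyopia
_PEAK_EXCESS = 0.5   # baseline peak must exceed 1 + this for the triadic call
_PEAK_DROP = 0.25    # fractional peak reduction for the triadic call
_STABLE_FRAC = 0.10  # "little changed" tolerance on the other species


def _short_range_g(curve: PcfCurve, n_bins: int = 3) -> float:
    g = curve.g_values[np.isfinite(curve.g_values)][:n_bins]
    return float(np.mean(g)) if g.size else np.nan


def cluster_extent(curve: PcfCurve) -> float:
    """First distance at which the conspecific g falls back through 1.

    0 when the pattern is not aggregated at the shortest defined distance;
    the largest binned distance if g never drops below 1.
    """
    mids = curve.r_mid
    g = curve.g_values
    started = False
    for m, gv in zip(mids, g):
        if not np.isfinite(gv):
            continue
        if not started:
            if gv <= 1.0:
                return 0.0
            started = True
            continue
        if gv < 1.0:
            return float(m)
    return float(mids[-1]) if started else 0.0


def peak_height(curve: PcfCurve) -> float:
    g = curve.g_values[np.isfinite(curve.g_values)]
    return float(np.max(g)) if g.size else np.nan


def classify_mechanism(
    baseline: dict[tuple[int, int], PcfCurve],
    focal: dict[tuple[int, int], PcfCurve],
    densities: tuple[float, float],
) -> MechanismCall:
    """Identify the spatial coexistence mechanism from PCF contrasts.

    ``baseline`` holds the PCFs of the long-range (mean-field-like) run and
    ``focal`` those of the short-range run, keyed by species pair (1,1),
    (2,2) and (1,2); ``densities`` are the stationary densities naming the
    rarer species.  Rules, checked in order:

    * heteromyopia — the dominant species' cluster extent shrinks markedly
      relative to baseline while the rare species stays aggregated;
    * triadic — the rare species' conspecific PCF peak flattens toward 1
      while the dominant's structure is little changed;
    * spatial segregation — both conspecific PCFs aggregated at short range,
      the cross PCF segregated, and near-equivalent species (proxied by a
      density ratio below 3);
    * none otherwise.
    """
    for key in ((1, 1), (2, 2), (1, 2)):
        if key not in baseline or key not in focal:
            raise ValueError(f"missing PCF for pair {key}")
        if not np.array_equal(baseline[key].r_edges, focal[key].r_edges):
            raise ValueError(f"mismatched bins for pair {key}")
    dom = 1 if densities[0] >= densities[1] else 2
    rare = 3 - dom
    ev = {
        "dominant": dom,
        "extent_dom_base": cluster_extent(baseline[(dom, dom)]),
        "extent_dom_focal": cluster_extent(focal[(dom, dom)]),
        "peak_rare_base": peak_height(baseline[(rare, rare)]),
        "peak_rare_focal": peak_height(focal[(rare, rare)]),
        "peak_dom_base": peak_height(baseline[(dom, dom)]),
        "peak_dom_focal": peak_height(focal[(dom, dom)]),
        "g11_short": _short_range_g(focal[(1, 1)]),
        "g22_short": _short_range_g(focal[(2, 2)]),
        "g12_short": _short_range_g(focal[(1, 2)]),
    }

    extent_drop = ev["extent_dom_base"] > 0 and (
        ev["extent_dom_base"] - ev["extent_dom_focal"]
    ) / ev["extent_dom_base"] >= _EXTENT_DROP
    rare_aggregated = _short_range_g(focal[(rare, rare)]) > _AGG
    rare_was_aggregated = _short_range_g(baseline[(rare, rare)]) > _AGG
    if extent_drop and rare_aggregated and rare_was_aggregated:
        return MechanismCall("heteromyopia", ev)

    base_excess = ev["peak_rare_base"] - 1.0
    peak_drop = base_excess > _PEAK_EXCESS and (
        ev["peak_rare_base"] - ev["peak_rare_focal"]
    ) / base_excess >= _PEAK_DROP
    dom_stable = (
        np.isfinite(ev["peak_dom_base"])
        and abs(ev["peak_dom_focal"] - ev["peak_dom_base"])
        <= _STABLE_FRAC * max(ev["peak_dom_base"], 1.0)
    )
    if peak_drop and dom_stable:
        return MechanismCall("triadic", ev)

    dmin, dmax = min(densities), max(densities)
    near_equivalent = dmin > 0 and dmax / dmin < 3.0
    if (
        ev["g11_short"] > _AGG
        and ev["g22_short"] > _AGG
        and ev["g12_short"] < _SEG
        and near_equivalent
    ):
        return MechanismCall("spatial_segregation", ev)

    return MechanismCall("none", ev)
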