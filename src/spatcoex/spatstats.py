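"""Second-order point-pattern statistics on the torus lattice.

Ripley's K counts, for each focal point, the partner points within distance
``r`` and normalises by the partner intensity; the pair correlation g(r) is
its discrete derivative per annulus, and the neighbourhood factor g_{a,b}(R)
is K(R) divided by the discrete integration area.  Because the lattice is
periodic, torus (minimum-image) distances are exact and no edge correction
is needed.  Annulus normalisers are *site counts*, not continuum ring areas:
on a grid the number of offsets falling in an annulus is the exact measure,
and continuum areas would bias g at small r.

Pair counts are computed by circular cross-correlation of occupancy
indicator grids (FFT), which enumerates every ordered pair exactly in
O(L^2 log L) regardless of the number of points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PointPattern",
    "PcfCurve",
    "torus_distance",
    "ripley_K",
    "pair_correlation",
    "neighbourhood_factor",
    "default_r_edges",
    "patterns_from_state",
    "mean_pcf",
    "save_pcf",
    "load_pcf",
]


def torus_distance(p, q, L: float) -> float:
    """Euclidean distance under the minimum-image convention."""
    dx = abs(p[0] - q[0])
    dy = abs(p[1] - q[1])
    dx = min(dx, L - dx)
    dy = min(dy, L - dy)
    return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class PointPattern:
    """A single-species point pattern on integer lattice sites."""

    points: np.ndarray  # (n, 2) integer coordinates in [0, L)
    species_label: int
    lattice_side: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.allclose(pts, np.round(pts)):
            raise ValueError("pattern coordinates must be integer lattice sites")
        pts = pts.astype(np.int64)
        if pts.size:
            if pts.min() < 0 or pts.max() >= self.lattice_side:
                raise ValueError("coordinates must lie in [0, L)")
            if len(np.unique(pts, axis=0)) != len(pts):
                raise ValueError("duplicate coordinates in pattern")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def density(self) -> float:
        return self.n / self.lattice_side**2

    def indicator(self) -> np.ndarray:
        grid = np.zeros((self.lattice_side, self.lattice_side))
        if self.n:
            grid[self.points[:, 0], self.points[:, 1]] = 1.0
        return grid


@dataclass
class PcfCurve:
    """Binned pair- or cross-pair-correlation estimate."""

    r_edges: np.ndarray   # len nb+1, starting at 0, strictly increasing
    g_values: np.ndarray  # len nb; NaN where the annulus holds no lattice site
    pair: tuple[int, int]
    n_points: tuple[int, int]
    annulus_sites: np.ndarray | None = None  # offsets per annulus (normaliser)
    pair_counts: np.ndarray | None = None    # ordered pairs per annulus

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


def default_r_edges(L: int) -> np.ndarray:
    """Unit-width annuli from 0 out to L/4 (annuli stay well populated)."""
    return np.arange(0.0, L / 4 + 1.0)


# ---------------------------------------------------------------------------
# exact ordered-pair counts via circular cross-correlation
# ---------------------------------------------------------------------------

def _offset_distance_grid(L: int) -> np.ndarray:
    """Minimum-image distance of every lattice offset (dx, dy)."""
    d = np.arange(L)
    d = np.minimum(d, L - d)
    return np.hypot(d[:, None], d[None, :])


def _pair_count_grid(a: PointPattern, b: PointPattern) -> np.ndarray:
    """C[dx, dy] = number of ordered pairs (p in a, q in b) with q = p + (dx, dy)."""
    fa = np.fft.rfft2(a.indicator())
    fb = np.fft.rfft2(b.indicator())
    c = np.fft.irfft2(np.conj(fa) * fb, s=(a.lattice_side, a.lattice_side))
    return np.rint(c).astype(np.int64)


def _check_pair(a: PointPattern, b: PointPattern) -> None:
    if a.lattice_side != b.lattice_side:
        raise ValueError("patterns must share lattice_side")


def ripley_K(pattern_a: PointPattern, pattern_b: PointPattern, r_grid) -> np.ndarray:
    """Ripley's K on the torus: K(r) = pairs within r / (lambda_b * n_a).

    For the univariate case (``pattern_a is pattern_b`` or equal points and
    label) the self-pair at zero offset is excluded; the cross case counts
    all (a-point, b-point) pairs.  Torus distances make the estimator exact
    without edge correction.
    """
    _check_pair(pattern_a, pattern_b)
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if pattern_a.n == 0 or pattern_b.n == 0:
        raise ValueError("K is undefined for an empty pattern (zero density)")
    if np.any(r_grid > pattern_a.lattice_side / 2):
        raise ValueError("r_grid must not exceed L/2 (torus distance is ambiguous beyond)")
    counts = _pair_count_grid(pattern_a, pattern_b)
    univariate = pattern_a.species_label == pattern_b.species_label
    if univariate:
        counts = counts.copy()
        counts[0, 0] -= pattern_a.n  # remove self pairs
    dist = _offset_distance_grid(pattern_a.lattice_side)
    out = np.empty(len(r_grid))
    for i, r in enumerate(r_grid):
        out[i] = counts[dist <= r].sum()
    return out / (pattern_b.density * pattern_a.n)


def pair_correlation(pattern_a: PointPattern, pattern_b: PointPattern, r_edges=None) -> PcfCurve:
    """Pair correlation per annulus ``(r_k, r_{k+1}]``.

    g = (mean partner count in the annulus per focal point) divided by
    (partner intensity x annulus site count); exactly the discrete
    derivative of K over the annulus (K uses ``d <= r``, so annuli are
    left-open).  The zero-distance offset never falls in an annulus, which
    excludes self pairs automatically.  g = 1 under independence, > 1 for
    aggregation, < 1 for segregation.  Annuli containing no lattice offset
    get NaN (undefined, flagged via ``annulus_sites == 0``).
    """
    _check_pair(pattern_a, pattern_b)
    if r_edges is None:
        r_edges = default_r_edges(pattern_a.lattice_side)
    r_edges = np.asarray(r_edges, dtype=float)
    if r_edges[0] != 0 or np.any(np.diff(r_edges) <= 0):
        raise ValueError("r_edges must start at 0 and be strictly increasing")
    if pattern_a.n == 0 or pattern_b.n == 0:
        raise ValueError("pair correlation is undefined for an empty pattern")
    counts = _pair_count_grid(pattern_a, pattern_b)
    dist = _offset_distance_grid(pattern_a.lattice_side)
    nb = len(r_edges) - 1
    pair_counts = np.zeros(nb, dtype=np.int64)
    site_counts = np.zeros(nb, dtype=np.int64)
    # left-open annuli: distance exactly on an edge belongs to the bin below
    which = np.searchsorted(r_edges, dist.ravel(), side="left") - 1
    flat_counts = counts.ravel()
    for k in range(nb):
        sel = which == k
        site_counts[k] = sel.sum()
        pair_counts[k] = flat_counts[sel].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        g = pair_counts / (pattern_a.n * pattern_b.density * site_counts)
    g = np.where(site_counts > 0, g, np.nan)
    return PcfCurve(
        r_edges=r_edges,
        g_values=g,
        pair=(pattern_a.species_label, pattern_b.species_label),
        n_points=(pattern_a.n, pattern_b.n),
        annulus_sites=site_counts,
        pair_counts=pair_counts,
    )


def neighbourhood_factor(pattern_a: PointPattern, pattern_b: PointPattern, radius: float) -> float:
    """Observed partner density within ``radius`` relative to the global mean.

    Equals K(radius) divided by the discrete integration area (the number of
    lattice sites within the radius, origin excluded — the same disc used by
    the simulator's dispersal and kill neighbourhoods).  1 under spatial
    independence; the weight entering the spatial Lotka-Volterra equations.
    """
    _check_pair(pattern_a, pattern_b)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if pattern_a.n == 0:
        raise ValueError("neighbourhood factor needs a non-empty focal pattern")
    if pattern_b.n == 0:
        raise ValueError("neighbourhood factor is 0/0 for an empty partner pattern")
    counts = _pair_count_grid(pattern_a, pattern_b)
    if pattern_a.species_label == pattern_b.species_label:
        counts = counts.copy()
        counts[0, 0] -= pattern_a.n
    dist = _offset_distance_grid(pattern_a.lattice_side)
    mask = (dist <= radius)
    mask[0, 0] = False  # focal site excluded from the disc
    area = int(mask.sum())
    pairs = int(counts[mask].sum())
    return pairs / (pattern_a.n * pattern_b.density * area)


# ---------------------------------------------------------------------------
# helpers bridging the simulator and ensembles
# ---------------------------------------------------------------------------

def patterns_from_state(state) -> dict[int, PointPattern]:
    """Split a lattice state into per-species point patterns (label -> pattern)."""
    out = {}
    for label in (1, 2):
        xs, ys = np.nonzero(state.occupancy == label)
        out[label] = PointPattern(
            np.column_stack([xs, ys]), label, state.occupancy.shape[0]
        )
    return out


def mean_pcf(curves: list[PcfCurve]) -> tuple[PcfCurve, np.ndarray]:
    """Pointwise ensemble mean of PCF curves plus the standard error per bin."""
    if not curves:
        raise ValueError("no curves to average")
    edges = curves[0].r_edges
    for c in curves[1:]:
        if not np.array_equal(c.r_edges, edges):
            raise ValueError("mismatched bins across ensemble")
    g = np.vstack([c.g_values for c in curves])
    mean = np.nanmean(g, axis=0)
    with np.errstate(invalid="ignore"):
        se = np.nanstd(g, axis=0, ddof=1) / np.sqrt(len(curves))
    avg = PcfCurve(
        r_edges=edges,
        g_values=mean,
        pair=curves[0].pair,
        n_points=curves[0].n_points,
        annulus_sites=curves[0].annulus_sites,
    )
    return avg, se


def save_pcf(curve: PcfCurve, path, stderr=None) -> None:
    df = pd.DataFrame(
        {
            "r_lo": curve.r_edges[:-1],
            "r_hi": curve.r_edges[1:],
            "g": curve.g_values,
            "stderr": stderr if stderr is not None else np.nan,
            "n_pairs": curve.pair_counts if curve.pair_counts is not None else -1,
        }
    )
    df.to_csv(path, index=False)


def load_pcf(path, pair=(0, 0)) -> PcfCurve:
    df = pd.read_csv(path)
    edges = np.append(df["r_lo"].to_numpy(), df["r_hi"].to_numpy()[-1])
    return PcfCurve(
        r_edges=edges,
        g_values=df["g"].to_numpy(),
        pair=tuple(pair),
        n_points=(0, 0),
    )
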