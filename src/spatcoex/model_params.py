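"""Parameterisation of the two-species lattice competition model.

The community is described by per-species demographic rates (birth ``b_i``,
intrinsic death ``d_i``), a dispersal radius ``Rb_i`` for offspring placement,
and a 2x2 active-competition structure: ``c[i, j]`` is the rate at which an
individual of species ``j`` attempts to kill an individual of species ``i``
within the competition radius ``Rc[i, j]``.  Species indices are 0-based in
code (species 1 -> index 0).

Specs are serialised to a strict YAML dialect; unknown keys are an error so
that typos in experiment configs fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SpeciesParams",
    "CompetitionParams",
    "ModelSpec",
    "RunConfig",
    "SpecError",
    "validate_spec",
    "load_spec",
    "save_spec",
    "default_spec",
    "flatten_spec",
]


class SpecError(ValueError):
    """A model specification violates an invariant or cannot be parsed."""


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic parameters of one species.

    Parameters
    ----------
    birth_rate
        Offspring-production attempts per individual per unit time (``b_i``).
    dispersal_radius
        Maximum Euclidean distance, in lattice units, at which offspring can
        be placed (``Rb_i``); the target site is drawn uniformly from the
        disc of this radius around the parent, excluding the parent's site.
    intrinsic_death_rate
        Death rate in the absence of competition (``d_i``).
    """

    birth_rate: float = 1.0
    dispersal_radius: float = 1.0
    intrinsic_death_rate: float = 0.1


@dataclass(frozen=True)
class CompetitionParams:
    """Active-competition rates and radii.

    ``rate[i][j]`` is ``c_{i,j}``: the rate at which an individual of species
    ``j`` acquires resources within ``radius[i][j]`` (``Rc_{i,j}``) and kills
    an individual of species ``i`` found at the drawn site.  Diagonal entries
    are the intra-specific case.
    """

    rate: tuple[tuple[float, float], tuple[float, float]] = ((0.2, 0.2), (0.2, 0.2))
    radius: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0))

    def rate_array(self) -> np.ndarray:
        return np.asarray(self.rate, dtype=float)

    def radius_array(self) -> np.ndarray:
        return np.asarray(self.radius, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterisation of the two-species community."""

    species: tuple[SpeciesParams, SpeciesParams] = (SpeciesParams(), SpeciesParams())
    competition: CompetitionParams = field(default_factory=CompetitionParams)
    lattice_side: int = 150
    initial_density: tuple[float, float] = (0.4, 0.4)

    # -- convenience accessors used throughout the package -----------------
    def birth_rates(self) -> np.ndarray:
        return np.array([s.birth_rate for s in self.species], dtype=float)

    def death_rates(self) -> np.ndarray:
        return np.array([s.intrinsic_death_rate for s in self.species], dtype=float)

    def dispersal_radii(self) -> np.ndarray:
        return np.array([s.dispersal_radius for s in self.species], dtype=float)

    def n_sites(self) -> int:
        return self.lattice_side * self.lattice_side

    def replace(self, **kwargs) -> "ModelSpec":
        return dataclasses.replace(self, **kwargs)

    def with_param(self, name: str, value: float) -> "ModelSpec":
        """Return a copy with one scalar parameter changed.

        ``name`` uses 1-based species labels as in the field's notation:
        ``b1``, ``b2``, ``d1``, ``d2``, ``Rb1``, ``Rb2``, ``c11``, ``c12``,
        ``c21``, ``c22``, ``Rc11``, ``Rc12``, ``Rc21``, ``Rc22``.
        """
        sp = list(self.species)
        if name in ("b1", "b2", "d1", "d2", "Rb1", "Rb2"):
            k = int(name[-1]) - 1
            fld = {"b": "birth_rate", "d": "intrinsic_death_rate", "R": "dispersal_radius"}[name[0]]
            sp[k] = dataclasses.replace(sp[k], **{fld: value})
            return self.replace(species=(sp[0], sp[1]))
        if name.startswith(("c", "Rc")) and name[-2:].isdigit():
            i, j = int(name[-2]) - 1, int(name[-1]) - 1
            rates = [list(r) for r in self.competition.rate]
            radii = [list(r) for r in self.competition.radius]
            if name.startswith("Rc"):
                radii[i][j] = value
            else:
                rates[i][j] = value
            comp = CompetitionParams(
                rate=(tuple(rates[0]), tuple(rates[1])),
                radius=(tuple(radii[0]), tuple(radii[1])),
            )
            return self.replace(competition=comp)
        raise SpecError(f"unknown parameter name: {name!r}")


@dataclass(frozen=True)
class RunConfig:
    """Controls for a single stochastic realisation.

    ``stop_window``/``stop_tolerance`` define the stationarity rule: the run
    stops once the net change in total community density across
    ``stop_window`` consecutive time steps falls below ``stop_tolerance``.
    ``max_generations`` is a hard cap (one generation = unit time times the
    smallest positive birth rate).
    """

    seed: int = 0
    stop_window: int = 20
    stop_tolerance: float = 1e-5
    max_generations: float = 10_000.0


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_spec(spec: ModelSpec) -> ModelSpec:
    """Check every model invariant; return ``spec`` unchanged if all hold.

    Raises :class:`SpecError` naming the first violated invariant.
    """
    for k, s in enumerate(spec.species, start=1):
        if s.birth_rate < 0:
            raise SpecError(f"negative rate: birth_rate of species {k}")
        if s.intrinsic_death_rate < 0:
            raise SpecError(f"negative rate: intrinsic_death_rate of species {k}")
        if s.dispersal_radius < 1:
            raise SpecError(f"dispersal_radius of species {k} must be >= 1")
    rates = spec.competition.rate_array()
    radii = spec.competition.radius_array()
    if rates.shape != (2, 2) or radii.shape != (2, 2):
        raise SpecError("competition rate/radius must be 2x2")
    if (rates < 0).any():
        raise SpecError("negative rate: competition rate")
    if (radii < 1).any():
        raise SpecError("competition radius must be >= 1")
    if spec.lattice_side < 4:
        raise SpecError("lattice_side must be >= 4")
    r1, r2 = spec.initial_density
    if r1 < 0 or r2 < 0:
        raise SpecError("initial densities must be >= 0")
    if r1 + r2 > 1:
        raise SpecError("initial densities exceed capacity")
    return spec


def validate_run(run: RunConfig) -> RunConfig:
    if run.stop_window < 1:
        raise SpecError("stop_window must be >= 1")
    if run.stop_tolerance <= 0:
        raise SpecError("stop_tolerance must be > 0")
    if run.max_generations < 1:
        raise SpecError("max_generations must be >= 1")
    return run


def default_spec(**overrides) -> ModelSpec:
    """The package's default symmetric community (see docs/methods.md)."""
    return validate_spec(ModelSpec(**overrides) if overrides else ModelSpec())


# ---------------------------------------------------------------------------
# serialisation (strict YAML)
# ---------------------------------------------------------------------------

_SPECIES_KEYS = {"birth_rate", "dispersal_radius", "intrinsic_death_rate"}
_TOP_KEYS = {"species", "competition", "lattice_side", "initial_density"}
_COMP_KEYS = {"rate", "radius"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SpecError(f"unknown key(s) {sorted(unknown)} in {where}")
    missing = allowed - set(mapping)
    if missing:
        raise SpecError(f"missing required key(s) {sorted(missing)} in {where}")


def _matrix(raw, where: str) -> tuple[tuple[float, float], tuple[float, float]]:
    try:
        m = [[float(raw[i][j]) for j in range(2)] for i in range(2)]
    except (TypeError, IndexError, KeyError, ValueError) as exc:
        raise SpecError(f"{where} must be a 2x2 matrix of numbers") from exc
    return (tuple(m[0]), tuple(m[1]))


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "species": [
            {
                "birth_rate": float(s.birth_rate),
                "dispersal_radius": float(s.dispersal_radius),
                "intrinsic_death_rate": float(s.intrinsic_death_rate),
            }
            for s in spec.species
        ],
        "competition": {
            "rate": [list(map(float, r)) for r in spec.competition.rate],
            "radius": [list(map(float, r)) for r in spec.competition.radius],
        },
        "lattice_side": int(spec.lattice_side),
        "initial_density": [float(x) for x in spec.initial_density],
    }


def spec_from_dict(raw: dict) -> ModelSpec:
    if not isinstance(raw, dict):
        raise SpecError("spec file must contain a mapping at top level")
    _check_keys(raw, _TOP_KEYS, "spec")
    sp_raw = raw["species"]
    if not isinstance(sp_raw, list) or len(sp_raw) != 2:
        raise SpecError("'species' must be a list of exactly two blocks")
    species = []
    for k, blk in enumerate(sp_raw, start=1):
        if not isinstance(blk, dict):
            raise SpecError(f"species block {k} must be a mapping")
        _check_keys(blk, _SPECIES_KEYS, f"species block {k}")
        species.append(
            SpeciesParams(
                birth_rate=float(blk["birth_rate"]),
                dispersal_radius=float(blk["dispersal_radius"]),
                intrinsic_death_rate=float(blk["intrinsic_death_rate"]),
            )
        )
    comp_raw = raw["competition"]
    if not isinstance(comp_raw, dict):
        raise SpecError("'competition' block must be a mapping")
    _check_keys(comp_raw, _COMP_KEYS, "competition block")
    comp = CompetitionParams(
        rate=_matrix(comp_raw["rate"], "competition.rate"),
        radius=_matrix(comp_raw["radius"], "competition.radius"),
    )
    dens = raw["initial_density"]
    try:
        dens = (float(dens[0]), float(dens[1]))
    except (TypeError, IndexError, ValueError) as exc:
        raise SpecError("'initial_density' must be a pair of numbers") from exc
    spec = ModelSpec(
        species=(species[0], species[1]),
        competition=comp,
        lattice_side=int(raw["lattice_side"]),
        initial_density=dens,
    )
    return validate_spec(spec)


def save_spec(spec: ModelSpec, path) -> None:
    validate_spec(spec)
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path) -> ModelSpec:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SpecError(f"malformed spec file {path}: {exc}") from exc
    return spec_from_dict(raw)


def flatten_spec(spec: ModelSpec) -> dict[str, float]:
    """Flat scalar view (column headers for sweep manifests / CSV export)."""
    out: dict[str, float] = {}
    for k, s in enumerate(spec.species, start=1):
        out[f"b{k}"] = s.birth_rate
        out[f"d{k}"] = s.intrinsic_death_rate
        out[f"Rb{k}"] = s.dispersal_radius
        out[f"rho0_{k}"] = spec.initial_density[k - 1]
    for i in range(2):
        for j in range(2):
            out[f"c{i + 1}{j + 1}"] = spec.competition.rate[i][j]
            out[f"Rc{i + 1}{j + 1}"] = spec.competition.radius[i][j]
    out["L"] = float(spec.lattice_side)
    return out
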