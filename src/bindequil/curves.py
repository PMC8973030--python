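"""Concentration sweeps, pie fractions and concentration tables.

A sweep evaluates one equilibrium system over a log-spaced grid of
either a *total* concentration (one independent equilibrium solve per
grid point) or a *free* concentration (species follow directly from the
free value through mass action, no root solve needed).  The y axis can
show absolute concentrations (log or linear scale) or, where the model
offers it, relative amounts of the protein's forms summing to one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .equilibria import (
    CompetingLigandsSpec,
    CompetingReceptorsSpec,
    EquilibriumState,
    HomodimerSpec,
    LigandBindingSpec,
    SystemSpec,
    solve,
)
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "SweepSpec",
    "SweepResult",
    "SpeciesInfo",
    "sweep",
    "pie_fractions",
    "concentration_table",
    "evaluate_point",
    "curve_names",
    "PROTEIN_FORMS",
]

#: Default number of grid points along a sweep axis.
DEFAULT_N_POINTS = 300

#: Default sweep range: the slider span of the interactive sliders, mol/L.
DEFAULT_X_MIN = 1e-9
DEFAULT_X_MAX = 1e-1

#: Plot floor for log-scale axes so zero concentrations stay displayable.
LOG_FLOOR = 1e-18

# Forms of each protein (denominator total -> species, with P2 counted
# twice via monomer-equivalents in fraction_of).
PROTEIN_FORMS: dict[type, dict[str, tuple[str, ...]]] = {
    HomodimerSpec: {"P": ("P", "P2")},
    LigandBindingSpec: {"P": ("P", "PL")},
    CompetingLigandsSpec: {"P": ("P", "PL", "PL'")},
    CompetingReceptorsSpec: {"P": ("P", "PL"), "P'": ("P'", "P'L")},
}

# Which spec field each axis choice drives, per model.
_TOTAL_FIELDS: dict[type, dict[str, str]] = {
    HomodimerSpec: {"P": "c_P"},
    LigandBindingSpec: {"P": "c_P", "L": "c_L"},
    CompetingLigandsSpec: {"P": "c_P", "L": "c_L", "L'": "c_Lp"},
    CompetingReceptorsSpec: {"P": "c_P", "P'": "c_Pp", "L": "c_L"},
}

# Free-concentration axes each applet offers: [P], [L] and [L].
_FREE_SPECIES: dict[type, str] = {
    HomodimerSpec: "P",
    LigandBindingSpec: "L",
    CompetingReceptorsSpec: "L",
}

_Y_MODES = ("absolute-log", "relative-linear", "absolute-linear")


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of one concentration sweep.

    ``x_variable`` is ``("total", species)`` or ``("free", species)``;
    free-concentration axes exist only for the models that expose them
    (homodimer: [P]; ligand binding and competing receptors: [L]).
    The relative-linear y scale is not offered for competing receptors,
    where absolute linear concentrations are shown instead.
    """

    system: SystemSpec
    x_variable: tuple[str, str] = ("total", "P")
    x_min: float = DEFAULT_X_MIN
    x_max: float = DEFAULT_X_MAX
    n_points: int = DEFAULT_N_POINTS
    y_mode: str = "relative-linear"
    set_x: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.x_min < self.x_max):
            raise ConfigurationError("require 0 < x_min < x_max")
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.y_mode not in _Y_MODES:
            raise ConfigurationError(f"unknown y_mode {self.y_mode!r}")
        kind, species = self.x_variable
        model = type(self.system)
        if kind == "total":
            if species not in _TOTAL_FIELDS[model]:
                raise ConfigurationError(
                    f"{model.__name__} has no total-concentration axis {species!r}"
                )
        elif kind == "free":
            if _FREE_SPECIES.get(model) != species:
                raise ConfigurationError(
                    f"{model.__name__} offers no free-concentration axis {species!r}"
                )
        else:
            raise ConfigurationError(f"unknown axis kind {kind!r}")
        if self.y_mode == "relative-linear" and model is CompetingReceptorsSpec:
            raise ConfigurationError(
                "relative scale is not offered for competing receptors; "
                "use absolute-linear"
            )


@dataclass(frozen=True)
class SweepResult:
    """Curves over a log-spaced axis plus the set-point equilibrium."""

    spec: SweepSpec
    x: np.ndarray
    series: Mapping[str, np.ndarray]
    set_x: float
    set_state: EquilibriumState | None


@dataclass(frozen=True)
class SpeciesInfo:
    """Optional molar masses (g/mol) of the elementary components P, P', L, L'.

    Complex masses are derived as the sum of their constituents, which
    is what conservation of total mass requires.
    """

    masses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masses.items():
            if not (m > 0):
                raise InvalidParameterError(f"molar mass of {name} must be > 0")

    def mass_of(self, species: str) -> float | None:
        """Molar mass of any species, composing complexes from parts."""
        composition = _COMPOSITION.get(species, (species,))
        total = 0.0
        for part in composition:
            if part not in self.masses:
                return None
            total += self.masses[part]
        return total


_COMPOSITION: dict[str, tuple[str, ...]] = {
    "P": ("P",),
    "P'": ("P'",),
    "L": ("L",),
    "L'": ("L'",),
    "P2": ("P", "P"),
    "PL": ("P", "L"),
    "PL'": ("P", "L'"),
    "P'L": ("P'", "L"),
}


def curve_names(model: type, y_mode: str) -> tuple[str, ...]:
    """Names of the series a sweep of this model produces."""
    if y_mode == "relative-linear":
        return PROTEIN_FORMS[model]["P"]
    # absolute scales show every species
    return {
        HomodimerSpec: ("P", "P2"),
        LigandBindingSpec: ("P", "L", "PL"),
        CompetingLigandsSpec: ("P", "L", "L'", "PL", "PL'"),
        CompetingReceptorsSpec: ("P", "P'", "L", "PL", "P'L"),
    }[model]


def _state_from_free(system: SystemSpec, free_value: float) -> dict[str, float]:
    """Species concentrations implied by one fixed free concentration.

    With the free value pinned, mass action determines every other
    species without solving a conservation equation.  The implied totals
    generally differ from the spec's; fractions are taken against the
    implied totals.
    """
    if isinstance(system, HomodimerSpec):
        P = free_value
        P2 = P * P / system.K_D
        return {"P": P, "P2": P2}
    if isinstance(system, LigandBindingSpec):
        L = free_value
        PL = system.c_P * L / (L + system.K_D)
        return {"P": system.c_P - PL, "L": L, "PL": PL}
    if isinstance(system, CompetingReceptorsSpec):
        L = free_value
        PL = system.c_P * L / (system.K_D + L)
        PpL = system.c_Pp * L / (system.K_Dp + L)
        return {
            "P": system.c_P - PL,
            "P'": system.c_Pp - PpL,
            "L": L,
            "PL": PL,
            "P'L": PpL,
        }
    raise ConfigurationError(
        f"{type(system).__name__} offers no free-concentration axis"
    )


def evaluate_point(
    system: SystemSpec,
    x_variable: tuple[str, str],
    x: float,
    y_mode: str,
    curve: str,
) -> float:
    """Value of one named curve at one axis point.

    This single evaluation path is shared by :func:`sweep` and the
    least-squares objective so fitted curves are exactly the plotted ones.
    """
    kind, axis_species = x_variable
    model = type(system)
    if kind == "total":
        sys_at_x = replace(system, **{_TOTAL_FIELDS[model][axis_species]: x})
        state = solve(sys_at_x)
        if y_mode == "relative-linear":
            return state.fraction_of(curve, "P")
        return state[curve]
    # free-concentration axis
    species = _state_from_free(system, x)
    if y_mode == "relative-linear":
        if isinstance(system, HomodimerSpec):
            total = species["P"] + 2.0 * species["P2"]
            weight = 2.0 if curve == "P2" else 1.0
            return weight * species[curve] / total if total > 0 else 0.0
        total = system.c_P
        return species[curve] / total
    return species[curve]


def sweep(spec: SweepSpec) -> SweepResult:
    """Evaluate all curves of a system over a log-uniform axis grid.

    Endpoints are included.  The set-point equilibrium (full state) is
    solved at ``set_x`` — defaulting to the geometric midpoint of the
    range — whenever the axis is a total concentration.
    """
    x = np.geomspace(spec.x_min, spec.x_max, spec.n_points)
    names = curve_names(type(spec.system), spec.y_mode)
    series = {
        name: np.array(
            [
                evaluate_point(spec.system, spec.x_variable, xi, spec.y_mode, name)
                for xi in x
            ]
        )
        for name in names
    }
    set_x = (
        spec.set_x
        if spec.set_x is not None
        else math.sqrt(spec.x_min * spec.x_max)
    )
    kind, axis_species = spec.x_variable
    if kind == "total":
        sys_at = replace(
            spec.system, **{_TOTAL_FIELDS[type(spec.system)][axis_species]: set_x}
        )
        set_state = solve(sys_at)
    else:
        set_state = None
    return SweepResult(spec=spec, x=x, series=series, set_x=set_x, set_state=set_state)


def pie_fractions(
    state: EquilibriumState, protein: str = "P"
) -> list[tuple[str, float]]:
    """Proportions of one protein's total across its forms.

    Homodimer fractions are monomer-equivalents ([P]/c_P and 2[P2]/c_P),
    so they always sum to one.
    """
    forms = PROTEIN_FORMS[type(state.spec)].get(protein)
    if forms is None:
        raise InvalidParameterError(
            f"{type(state.spec).__name__} has no protein {protein!r}"
        )
    return [(name, state.fraction_of(name, protein)) for name in forms]


def concentration_table(
    state: EquilibriumState, info: SpeciesInfo | None = None
) -> list[dict]:
    """One row per species: molar concentration and, when the component
    masses are known, the mass concentration in g/L."""
    rows = []
    for name, conc in state.species.items():
        row: dict = {"species": name, "molar": conc}
        if info is not None:
            m = info.mass_of(name)
            if m is not None:
                row["molar_mass"] = m
                row["mass"] = conc * m
        rows.append(row)
    return rows
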