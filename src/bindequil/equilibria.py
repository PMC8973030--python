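"""Mass-action equilibrium solvers for four protein association systems.

The four systems are

* homodimerization          2P ⇌ P2
* ligand binding            P + L ⇌ PL
* competing ligands         P + L ⇌ PL,  P + L' ⇌ PL'
* competing receptors       P + L ⇌ PL,  P' + L ⇌ P'L

Each solver maps total (analytic) concentrations and dissociation
constants to the unique non-negative equilibrium state.  The two-species
systems reduce to quadratics solved in closed form; the three-species
competition systems reduce to a monotone scalar equation on a guaranteed
bracket, solved by a safeguarded Newton iteration with bisection
fallback.

All concentrations are in mol/L, dissociation constants in mol/L, and
free energies in J/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import (
    BracketError,
    InvalidParameterError,
    NumericalFailureError,
    UndefinedSpecificityError,
)

__all__ = [
    "HomodimerSpec",
    "LigandBindingSpec",
    "CompetingLigandsSpec",
    "CompetingReceptorsSpec",
    "EquilibriumState",
    "ThermoContext",
    "solve",
    "solve_homodimer",
    "solve_ligand_binding",
    "solve_competing_ligands",
    "solve_competing_receptors",
    "bound_fraction_at_free_ligand",
    "specificity",
    "crossover_free_ligand",
    "assoc_const",
    "dissoc_const",
    "gibbs_energy",
    "solve_bracketed_root",
]

#: Gas constant in J K^-1 mol^-1.
GAS_CONSTANT = 8.314

#: Default temperature (25 degrees Celsius) in kelvin.
DEFAULT_TEMPERATURE = 298.15


def _require_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")


def _require_pos(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class HomodimerSpec:
    """Self-association 2P ⇌ P2.

    Parameters
    ----------
    c_P : float
        Total protein concentration in monomer-equivalents, mol/L.
    K_D : float
        Dimer dissociation constant [P]^2/[P2], mol/L.
    """

    c_P: float
    K_D: float

    def __post_init__(self) -> None:
        _require_nonneg("c_P", self.c_P)
        _require_pos("K_D", self.K_D)

    totals = property(lambda self: {"P": self.c_P})


@dataclass(frozen=True)
class LigandBindingSpec:
    """One receptor, one ligand: P + L ⇌ PL."""

    c_P: float
    c_L: float
    K_D: float

    def __post_init__(self) -> None:
        _require_nonneg("c_P", self.c_P)
        _require_nonneg("c_L", self.c_L)
        _require_pos("K_D", self.K_D)

    totals = property(lambda self: {"P": self.c_P, "L": self.c_L})


@dataclass(frozen=True)
class CompetingLigandsSpec:
    """Two ligands compete for one receptor: P + L ⇌ PL, P + L' ⇌ PL'.

    ``K_D`` belongs to the PL complex and ``K_Dp`` to PL'.
    """

    c_P: float
    c_L: float
    c_Lp: float
    K_D: float
    K_Dp: float

    def __post_init__(self) -> None:
        _require_nonneg("c_P", self.c_P)
        _require_nonneg("c_L", self.c_L)
        _require_nonneg("c_Lp", self.c_Lp)
        _require_pos("K_D", self.K_D)
        _require_pos("K_Dp", self.K_Dp)

    totals = property(
        lambda self: {"P": self.c_P, "L": self.c_L, "L'": self.c_Lp}
    )


@dataclass(frozen=True)
class CompetingReceptorsSpec:
    """One ligand binds two receptors: P + L ⇌ PL, P' + L ⇌ P'L.

    ``K_D`` belongs to the PL complex and ``K_Dp`` to P'L.  Modelling
    nonspecific binding is the canonical use: make P' abundant and weak
    (large ``c_Pp``, large ``K_Dp``).
    """

    c_P: float
    c_Pp: float
    c_L: float
    K_D: float
    K_Dp: float

    def __post_init__(self) -> None:
        _require_nonneg("c_P", self.c_P)
        _require_nonneg("c_Pp", self.c_Pp)
        _require_nonneg("c_L", self.c_L)
        _require_pos("K_D", self.K_D)
        _require_pos("K_Dp", self.K_Dp)

    totals = property(
        lambda self: {"P": self.c_P, "P'": self.c_Pp, "L": self.c_L}
    )


SystemSpec = (
    HomodimerSpec | LigandBindingSpec | CompetingLigandsSpec | CompetingReceptorsSpec
)


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations of every species in one system.

    ``species`` maps species names (P, P', P2, L, L', PL, PL', P'L as
    applicable) to concentrations in mol/L.  ``spec`` is the system the
    state was solved from.
    """

    species: Mapping[str, float]
    spec: SystemSpec

    def __getitem__(self, name: str) -> float:
        return self.species[name]

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def fraction_of(self, complex_or_free: str, total_species: str) -> float:
        """Fraction of ``total_species``'s total present as one form.

        Dimers count twice toward the protein total (monomer-equivalents).
        """
        total = self.spec.totals[total_species]
        if total == 0:
            raise InvalidParameterError(
                f"total of {total_species} is zero; fractions undefined"
            )
        weight = 2.0 if complex_or_free == "P2" else 1.0
        return weight * self.species[complex_or_free] / total


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: gas constant R (J/K/mol) and temperature T (K)."""

    R: float = GAS_CONSTANT
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        _require_pos("T", self.T)
        _require_pos("R", self.R)


# ---------------------------------------------------------------------------
# Root finding: Newton's method safeguarded by bisection on a bracket.
# ---------------------------------------------------------------------------

_DERIVATIVE_FLOOR = 1e-300


def solve_bracketed_root(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    rel_tol: float = 1e-12,
    max_iter: int = 200,
    fprime: Callable[[float], float] | None = None,
    x0: float | None = None,
) -> float:
    """Find the root of a monotone scalar function on a bracket.

    Newton steps are taken whenever a derivative is available and the
    step stays inside the current bracket; otherwise the iteration falls
    back to a bisection step, which guarantees convergence.  Without an
    analytic derivative a secant-style finite difference drives the
    Newton step.

    Parameters
    ----------
    f : callable
        Function whose root is sought; must change sign on [lo, hi]
        (or vanish at an endpoint).
    lo, hi : float
        Bracket endpoints, lo < hi.
    rel_tol : float
        Relative tolerance on the root variable.
    max_iter : int
        Iteration cap; exceeding it raises :class:`NumericalFailureError`.
    fprime : callable, optional
        Analytic derivative of ``f``.
    x0 : float, optional
        Initial guess (warm start); defaults to the bracket midpoint.
    """
    flo = f(lo)
    fhi = f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise BracketError(
            f"f({lo!r}) = {flo!r} and f({hi!r}) = {fhi!r} have the same sign"
        )

    x = 0.5 * (lo + hi) if x0 is None else min(max(x0, lo), hi)
    fx = f(x)
    for _ in range(max_iter):
        if fx == 0.0:
            return x
        # shrink the bracket around the sign change
        if flo * fx < 0:
            hi, fhi = x, fx
        else:
            lo, flo = x, fx
        if hi - lo <= rel_tol * max(abs(lo), abs(hi)):
            return 0.5 * (lo + hi)

        x_new = None
        if fprime is not None:
            d = fprime(x)
            if abs(d) > _DERIVATIVE_FLOOR:
                cand = x - fx / d
                if lo < cand < hi:
                    x_new = cand
        else:
            # finite-difference Newton (secant against a nearby point)
            h = (hi - lo) * 1e-6
            if h > 0:
                d = (f(x + h) - fx) / h
                if abs(d) > _DERIVATIVE_FLOOR:
                    cand = x - fx / d
                    if lo < cand < hi:
                        x_new = cand
        if x_new is None:
            x_new = 0.5 * (lo + hi)  # bisection fallback
        x = x_new
        fx = f(x)
    raise NumericalFailureError(
        f"root iteration did not converge within {max_iter} steps"
    )


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def solve_homodimer(spec: HomodimerSpec) -> EquilibriumState:
    """Solve 2P ⇌ P2 in closed form.

    The conservation relation [P] + 2[P]^2/K_D = c_P is quadratic in the
    free monomer; the physically meaningful (positive) root is

        [P] = (-K_D + sqrt(K_D^2 + 8 K_D c_P)) / 4.
    """
    cP, KD = spec.c_P, spec.K_D
    if cP == 0.0:
        return EquilibriumState({"P": 0.0, "P2": 0.0}, spec)
    # Conjugate form avoids cancellation when K_D << c_P.
    P = 2.0 * KD * cP / (KD + math.sqrt(KD * KD + 8.0 * KD * cP))
    P2 = (cP - P) / 2.0
    return EquilibriumState({"P": P, "P2": max(P2, 0.0)}, spec)


def solve_ligand_binding(spec: LigandBindingSpec) -> EquilibriumState:
    """Solve P + L ⇌ PL in closed form.

    [PL] is the smaller root of x^2 - (c_P + c_L + K_D) x + c_P c_L = 0,
    evaluated in the cancellation-free conjugate form

        [PL] = 2 c_P c_L / (S + sqrt(S^2 - 4 c_P c_L)),  S = c_P + c_L + K_D.

    The larger root would exceed min(c_P, c_L) and is unphysical.
    """
    cP, cL, KD = spec.c_P, spec.c_L, spec.K_D
    if cP == 0.0 or cL == 0.0:
        return EquilibriumState({"P": cP, "L": cL, "PL": 0.0}, spec)
    S = cP + cL + KD
    disc = S * S - 4.0 * cP * cL
    PL = 2.0 * cP * cL / (S + math.sqrt(max(disc, 0.0)))
    return EquilibriumState(
        {"P": cP - PL, "L": cL - PL, "PL": PL}, spec
    )


def bound_fraction_at_free_ligand(L_free: float, K_D: float) -> float:
    """1:1 binding isotherm: receptor occupancy at a given *free* ligand level.

    Returns L/(L + K_D); equals 1/2 exactly when the free ligand
    concentration equals K_D.
    """
    _require_nonneg("L_free", L_free)
    _require_pos("K_D", K_D)
    return L_free / (L_free + K_D)


def _competition_root(
    total: float,
    terms: tuple[tuple[float, float], tuple[float, float]],
) -> float:
    """Root of x (1 + c1/(K1+x) + c2/(K2+x)) = total on (0, total].

    The left side is strictly increasing in x, so the root is unique.
    ``terms`` holds the (total, K_D) pairs of the two competitors.
    """
    (c1, K1), (c2, K2) = terms

    def g(x: float) -> float:
        return x * (1.0 + c1 / (K1 + x) + c2 / (K2 + x)) - total

    def gprime(x: float) -> float:
        return (
            1.0
            + c1 * K1 / (K1 + x) ** 2
            + c2 * K2 / (K2 + x) ** 2
        )

    return solve_bracketed_root(g, 0.0, total, rel_tol=1e-12, fprime=gprime)


def solve_competing_ligands(spec: CompetingLigandsSpec) -> EquilibriumState:
    """Solve the two-ligand competition P + L ⇌ PL, P + L' ⇌ PL'.

    Eliminating the complexes via mass action reduces the coupled cubic
    to a single monotone equation for the free receptor [P], solved
    numerically on the bracket (0, c_P].
    """
    cP, cL, cLp = spec.c_P, spec.c_L, spec.c_Lp
    KD, KDp = spec.K_D, spec.K_Dp
    if cP == 0.0:
        return EquilibriumState(
            {"P": 0.0, "L": cL, "L'": cLp, "PL": 0.0, "PL'": 0.0}, spec
        )
    P = _competition_root(cP, ((cL, KD), (cLp, KDp)))
    L = cL * KD / (KD + P)
    Lp = cLp * KDp / (KDp + P)
    return EquilibriumState(
        {
            "P": P,
            "L": L,
            "L'": Lp,
            "PL": P * L / KD,
            "PL'": P * Lp / KDp,
        },
        spec,
    )


def solve_competing_receptors(spec: CompetingReceptorsSpec) -> EquilibriumState:
    """Solve the two-receptor competition P + L ⇌ PL, P' + L ⇌ P'L.

    Symmetric to :func:`solve_competing_ligands` with the roles of
    receptor and ligand exchanged: the monotone scalar unknown is the
    free ligand [L] on (0, c_L].
    """
    cP, cPp, cL = spec.c_P, spec.c_Pp, spec.c_L
    KD, KDp = spec.K_D, spec.K_Dp
    if cL == 0.0:
        return EquilibriumState(
            {"P": cP, "P'": cPp, "L": 0.0, "PL": 0.0, "P'L": 0.0}, spec
        )
    L = _competition_root(cL, ((cP, KD), (cPp, KDp)))
    PL = cP * L / (KD + L)
    PpL = cPp * L / (KDp + L)
    return EquilibriumState(
        {
            "P": cP - PL,
            "P'": cPp - PpL,
            "L": L,
            "PL": PL,
            "P'L": PpL,
        },
        spec,
    )


_SOLVERS: dict[type, Callable] = {
    HomodimerSpec: solve_homodimer,
    LigandBindingSpec: solve_ligand_binding,
    CompetingLigandsSpec: solve_competing_ligands,
    CompetingReceptorsSpec: solve_competing_receptors,
}


def solve(spec: SystemSpec) -> EquilibriumState:
    """Dispatch to the solver matching the spec's system type."""
    try:
        solver = _SOLVERS[type(spec)]
    except KeyError:  # pragma: no cover - defensive
        raise InvalidParameterError(f"unknown system spec {type(spec).__name__}")
    return solver(spec)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def specificity(state: EquilibriumState) -> float:
    """Specificity factor α_s = [PL]/[P'L] of a two-receptor competition.

    Quantifies how strongly the ligand prefers the high-affinity
    receptor at the given conditions; decreases toward c_P/c_P' as the
    ligand saturates both receptors.
    """
    if "P'L" not in state or "PL" not in state:
        raise InvalidParameterError(
            "specificity requires a competing-receptors equilibrium state"
        )
    PpL = state["P'L"]
    if PpL == 0.0:
        raise UndefinedSpecificityError(
            "no low-affinity complex present; specificity is unbounded"
        )
    return state["PL"] / PpL


def crossover_free_ligand(
    c_P: float, c_Pp: float, K_D: float, K_Dp: float
) -> float | None:
    """Free-ligand level at which the two complexes are equally abundant.

    Setting c_P [L]/(K_D+[L]) = c_P' [L]/(K_D'+[L]) gives

        [L] = (c_P K_D' - c_P' K_D) / (c_P' - c_P).

    Returns None when the curves never cross at a finite positive [L]
    (equal receptor totals, or a non-positive closed-form value).
    """
    _require_nonneg("c_P", c_P)
    _require_nonneg("c_Pp", c_Pp)
    _require_pos("K_D", K_D)
    _require_pos("K_Dp", K_Dp)
    denom = c_Pp - c_P
    if denom == 0.0:
        return None
    x = (c_P * K_Dp - c_Pp * K_D) / denom
    return x if x > 0.0 else None


def assoc_const(K_D: float) -> float:
    """Association constant K_A = 1/K_D, L/mol."""
    _require_pos("K_D", K_D)
    return 1.0 / K_D


def dissoc_const(K_A: float) -> float:
    """Dissociation constant K_D = 1/K_A, mol/L."""
    _require_pos("K_A", K_A)
    return 1.0 / K_A


def gibbs_energy(K_D: float, ctx: ThermoContext | None = None) -> float:
    """Binding free energy ΔG = R T ln K_D, J/mol.

    By convention the numerical value of K_D in mol/L enters the
    logarithm with its unit discarded; sub-molar constants therefore
    give negative (favourable) free energies.
    """
    _require_pos("K_D", K_D)
    if ctx is None:
        ctx = ThermoContext()
    return ctx.R * ctx.T * math.log(K_D)
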