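"""Solver correctness: closed forms, cubic roots, conservation, thermo."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindequil as bq
from bindequil.errors import (
    BracketError,
    InvalidParameterError,
    UndefinedSpecificityError,
)

from conftest import (
    oracle_binding_complex,
    oracle_competing_ligands_free_P,
    oracle_competing_receptors_free_L,
    oracle_homodimer_free_monomer,
    pure_bisection,
)

conc = st.floats(min_value=1e-9, max_value=1e-1)
kd = st.floats(min_value=1e-9, max_value=1e-1)


def check_conservation(state, rel=1e-9):
    """Every total equals the sum of its free and complexed forms."""
    sums = {name: 0.0 for name in state.spec.totals}
    for species, value in state.species.items():
        assert value >= 0
        for component in _components(species):
            sums[component] += value
    for name, total in state.spec.totals.items():
        assert sums[name] == pytest.approx(total, rel=rel, abs=1e-30)


def _components(species):
    if species == "P2":
        return ("P", "P")
    if species in ("P", "P'", "L", "L'"):
        return (species,)
    if species == "PL":
        return ("P", "L")
    if species == "PL'":
        return ("P", "L'")
    if species == "P'L":
        return ("P'", "L")
    raise AssertionError(species)


def check_mass_action(state, rel=1e-6):
    """Free*free/complex reproduces each K_D."""
    spec = state.spec
    s = state.species
    pairs = []
    if "P2" in s:
        pairs.append((s["P"] * s["P"], s["P2"], spec.K_D))
    if "PL" in s:
        pairs.append((s["P"] * s["L"], s["PL"], spec.K_D))
    if "PL'" in s:
        pairs.append((s["P"] * s["L'"], s["PL'"], spec.K_Dp))
    if "P'L" in s:
        pairs.append((s["P'"] * s["L"], s["P'L"], spec.K_Dp))
    for product, complex_conc, K in pairs:
        if complex_conc > 1e-300:
            assert product / complex_conc == pytest.approx(K, rel=rel)


class TestHomodimer:
    @pytest.mark.parametrize(
        "c_P,K_D,monomer_frac",
        [
            (1.0e-4, 1.0e-5, 0.200),   # 80.0% dimerized
            (8.0e-3, 8.0e-4, 0.200),   # exact: 20% monomer
            (1.2e-4, 8.0e-4, 0.8054),  # 19.5% dimer
            (4.0e-5, 1.6e-8, 0.0140),  # 98.6% dimer
        ],
    )
    def test_worked_examples(self, c_P, K_D, monomer_frac):
        state = bq.solve_homodimer(bq.HomodimerSpec(c_P, K_D))
        assert state.fraction_of("P", "P") == pytest.approx(monomer_frac, abs=5e-4)
        check_conservation(state)
        check_mass_action(state)

    def test_closed_form_free_monomer(self):
        c_P, K_D = 1.0e-4, 1.0e-5
        state = bq.solve_homodimer(bq.HomodimerSpec(c_P, K_D))
        expected = (-K_D + math.sqrt(K_D * K_D + 8 * K_D * c_P)) / 4
        assert state["P"] == pytest.approx(expected, rel=1e-12)

    def test_empty_system(self):
        state = bq.solve_homodimer(bq.HomodimerSpec(0.0, 1e-5))
        assert state["P"] == 0.0 and state["P2"] == 0.0

    @pytest.mark.parametrize("K_D", [1e-8, 1e-5, 1e-2])
    def test_half_dimerized_when_total_equals_kd(self, K_D):
        # at c_P = K_D the monomer fraction is exactly 1/2 ([P] = K_D/2)
        state = bq.solve_homodimer(bq.HomodimerSpec(K_D, K_D))
        assert state.fraction_of("P", "P") == pytest.approx(0.5, rel=1e-12)

    @given(c_P=conc, K_D=kd)
    @settings(max_examples=100, derandomize=True)
    def test_matches_bisection_oracle(self, c_P, K_D):
        state = bq.solve_homodimer(bq.HomodimerSpec(c_P, K_D))
        assert state["P"] == pytest.approx(
            oracle_homodimer_free_monomer(c_P, K_D), rel=1e-9
        )

    def test_bound_fraction_monotone_in_total(self):
        K_D = 1e-5
        grid = np.geomspace(1e-9, 1e-1, 200)
        fracs = [
            bq.solve_homodimer(bq.HomodimerSpec(c, K_D)).fraction_of("P2", "P")
            for c in grid
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            bq.HomodimerSpec(-1e-6, 1e-5)
        with pytest.raises(InvalidParameterError):
            bq.HomodimerSpec(1e-6, 0.0)


class TestLigandBinding:
    def test_saturation_example(self):
        state = bq.solve_ligand_binding(bq.LigandBindingSpec(1.2e-6, 4.5e-6, 4.5e-7))
        assert state.fraction_of("PL", "P") == pytest.approx(0.884, abs=5e-4)
        check_conservation(state)
        check_mass_action(state)

    def test_no_ligand_means_no_complex(self):
        state = bq.solve_ligand_binding(bq.LigandBindingSpec(1e-6, 0.0, 1e-7))
        assert state["PL"] == 0.0 and state["P"] == 1e-6

    def test_derived_bound_fraction(self):
        # brute-force bisection gives [PL] ≈ 3.675e-5 here
        c_P, c_L, K_D = 4.0e-5, 1.5e-4, 1.0e-5
        state = bq.solve_ligand_binding(bq.LigandBindingSpec(c_P, c_L, K_D))
        assert state["PL"] == pytest.approx(
            oracle_binding_complex(c_P, c_L, K_D), rel=1e-9
        )
        assert state.fraction_of("PL", "P") == pytest.approx(0.919, abs=1e-3)

    @given(c_P=conc, c_L=conc, K_D=kd)
    @settings(max_examples=100, derandomize=True)
    def test_matches_bisection_oracle(self, c_P, c_L, K_D):
        state = bq.solve_ligand_binding(bq.LigandBindingSpec(c_P, c_L, K_D))
        assert state["PL"] == pytest.approx(
            oracle_binding_complex(c_P, c_L, K_D), rel=1e-9, abs=1e-30
        )
        assert 0 <= state["PL"] <= min(c_P, c_L) * (1 + 1e-12)

    def test_complex_monotone_in_ligand(self):
        grid = np.geomspace(1e-9, 1e-1, 200)
        pl = [
            bq.solve_ligand_binding(bq.LigandBindingSpec(1e-5, c, 1e-6))["PL"]
            for c in grid
        ]
        assert all(b >= a for a, b in zip(pl, pl[1:]))

    def test_isotherm(self):
        assert bq.bound_fraction_at_free_ligand(1e-5, 1e-5) == 0.5
        assert bq.bound_fraction_at_free_ligand(0.0, 1e-5) == 0.0
        assert bq.bound_fraction_at_free_ligand(1e-4, 1e-5) == pytest.approx(10 / 11)


class TestCompetingLigands:
    def test_radioligand_example(self):
        spec = bq.CompetingLigandsSpec(1.0e-6, 5.0e-6, 1.0e-4, 1.0e-7, 2.0e-5)
        state = bq.solve_competing_ligands(spec)
        assert state.fraction_of("PL", "P") == pytest.approx(0.873, abs=5e-4)
        assert state.fraction_of("PL'", "P") == pytest.approx(0.106, abs=5e-4)
        assert state.fraction_of("P", "P") == pytest.approx(0.021, abs=5e-4)
        check_conservation(state)
        check_mass_action(state)

    def test_gas_displacement_example(self):
        # CO displacing O2: 10% carboxy-complex at c_L = 9e-4
        spec = bq.CompetingLigandsSpec(9.0e-3, 9.0e-4, 8.6e-3, 1.3e-9, 3.1e-7)
        state = bq.solve_competing_ligands(spec)
        assert 100 * state.fraction_of("PL", "P") == pytest.approx(10.0, abs=0.05)

    def test_degenerate_competitor_reduces_to_two_species(self):
        spec = bq.CompetingLigandsSpec(3e-6, 7e-6, 0.0, 2e-7, 5e-5)
        state = bq.solve_competing_ligands(spec)
        ref = bq.solve_ligand_binding(bq.LigandBindingSpec(3e-6, 7e-6, 2e-7))
        for name in ("P", "L", "PL"):
            assert state[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-30)
        assert state["PL'"] == 0.0

    @given(c_P=conc, c_L=conc, c_Lp=conc, K_D=kd, K_Dp=kd)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bisection_oracle(self, c_P, c_L, c_Lp, K_D, K_Dp):
        state = bq.solve_competing_ligands(
            bq.CompetingLigandsSpec(c_P, c_L, c_Lp, K_D, K_Dp)
        )
        assert state["P"] == pytest.approx(
            oracle_competing_ligands_free_P(c_P, c_L, c_Lp, K_D, K_Dp), rel=1e-9
        )
        check_conservation(state)
        check_mass_action(state)


class TestCompetingReceptors:
    def test_two_receptor_saturations(self):
        spec = bq.CompetingReceptorsSpec(1.0e-6, 4.5e-5, 2.0e-6, 1.0e-7, 8.0e-5)
        state = bq.solve_competing_receptors(spec)
        assert 100 * state.fraction_of("PL", "P") == pytest.approx(87.8, abs=0.05)
        assert 100 * state.fraction_of("P'L", "P'") == pytest.approx(0.9, abs=0.05)
        # free ligand cross-checked against the brute-force oracle
        assert state["L"] == pytest.approx(
            oracle_competing_receptors_free_L(1.0e-6, 4.5e-5, 2.0e-6, 1.0e-7, 8.0e-5),
            rel=1e-9,
        )
        check_conservation(state)
        check_mass_action(state)

    def test_degenerate_receptor_reduces_to_two_species(self):
        state = bq.solve_competing_receptors(
            bq.CompetingReceptorsSpec(3e-6, 0.0, 7e-6, 2e-7, 5e-5)
        )
        ref = bq.solve_ligand_binding(bq.LigandBindingSpec(3e-6, 7e-6, 2e-7))
        for name in ("P", "L", "PL"):
            assert state[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-30)

    @given(c_P=conc, c_Pp=conc, c_L=conc, K_D=kd, K_Dp=kd)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bisection_oracle(self, c_P, c_Pp, c_L, K_D, K_Dp):
        state = bq.solve_competing_receptors(
            bq.CompetingReceptorsSpec(c_P, c_Pp, c_L, K_D, K_Dp)
        )
        assert state["L"] == pytest.approx(
            oracle_competing_receptors_free_L(c_P, c_Pp, c_L, K_D, K_Dp), rel=1e-9
        )
        check_conservation(state)
        check_mass_action(state)


class TestSpecificity:
    FIG4 = dict(c_P=1.0e-6, c_Pp=4.5e-5, K_D=1.0e-7, K_Dp=8.0e-5)

    def _alpha(self, c_L):
        state = bq.solve_competing_receptors(
            bq.CompetingReceptorsSpec(c_L=c_L, **self.FIG4)
        )
        return bq.specificity(state)

    def test_reference_value(self):
        assert self._alpha(2.0e-6) == pytest.approx(2.2, abs=0.05)

    def test_equal_affinities_give_concentration_ratio(self):
        for c_L in (1e-8, 1e-6, 1e-4):
            state = bq.solve_competing_receptors(
                bq.CompetingReceptorsSpec(2e-6, 8e-6, c_L, 1e-7, 1e-7)
            )
            assert bq.specificity(state) == pytest.approx(2e-6 / 8e-6, rel=1e-9)

    def test_strictly_decreasing_with_ligand(self):
        alphas = [self._alpha(c) for c in np.geomspace(1e-9, 1e-1, 60)]
        assert all(b < a for a, b in zip(alphas, alphas[1:]))

    def test_limits(self):
        p = self.FIG4
        low_limit = p["c_P"] * p["K_Dp"] / (p["c_Pp"] * p["K_D"])  # ≈ 17.8
        assert self._alpha(1e-12) == pytest.approx(low_limit, rel=1e-3)
        assert self._alpha(1e2) == pytest.approx(p["c_P"] / p["c_Pp"], rel=1e-2)

    def test_undefined_when_no_weak_complex(self):
        state = bq.solve_competing_receptors(
            bq.CompetingReceptorsSpec(1e-6, 0.0, 1e-6, 1e-7, 1e-5)
        )
        with pytest.raises(UndefinedSpecificityError):
            bq.specificity(state)

    def test_requires_competing_receptors_state(self):
        state = bq.solve_homodimer(bq.HomodimerSpec(1e-5, 1e-5))
        with pytest.raises(InvalidParameterError):
            bq.specificity(state)


class TestCrossover:
    def test_reference_value(self):
        x = bq.crossover_free_ligand(1.0e-6, 4.5e-5, 1.0e-7, 8.0e-5)
        assert x == pytest.approx(1.716e-6, abs=1e-9)
        # cross-check: the two complexes really are equal at x
        f = lambda L: 1.0e-6 * L / (1.0e-7 + L) - 4.5e-5 * L / (8.0e-5 + L)
        assert f(x) == pytest.approx(0.0, abs=1e-15)

    def test_equal_totals_never_cross(self):
        assert bq.crossover_free_ligand(1e-6, 1e-6, 1e-7, 8e-5) is None

    def test_negative_closed_form_rejected(self):
        # closed form gives -1e-7 here
        assert bq.crossover_free_ligand(1e-6, 2e-6, 1e-7, 1e-7) is None


class TestThermo:
    def test_association_constant_roundtrip(self):
        assert bq.assoc_const(4.5e-7) == pytest.approx(2.2e6, rel=0.02)
        assert bq.assoc_const(1.0) == 1.0
        assert bq.dissoc_const(7.5e8) == pytest.approx(1.3e-9, rel=0.03)
        assert bq.dissoc_const(bq.assoc_const(3.7e-5)) == pytest.approx(3.7e-5)

    @pytest.mark.parametrize(
        "K_D,kj_per_mol",
        [(1.6e-8, -44.5), (4.5e-7, -36.2), (1.0, 0.0)],
    )
    def test_gibbs_energy(self, K_D, kj_per_mol):
        dg = bq.gibbs_energy(K_D, bq.ThermoContext())
        assert dg / 1e3 == pytest.approx(kj_per_mol, abs=0.05)

    def test_invalid_inputs(self):
        for fn in (bq.assoc_const, bq.dissoc_const, bq.gibbs_energy):
            with pytest.raises(InvalidParameterError):
                fn(0.0)
            with pytest.raises(InvalidParameterError):
                fn(-1.0)
        with pytest.raises(InvalidParameterError):
            bq.ThermoContext(T=-1.0)


class TestRootFinder:
    def test_classic_cubic(self):
        root = bq.solve_bracketed_root(lambda x: x**3 - 2 * x - 5, 2.0, 3.0)
        assert root == pytest.approx(2.0945515, abs=1e-7)

    @pytest.mark.parametrize("a", [2.1, 2.5, 2.999])
    def test_linear(self, a):
        assert bq.solve_bracketed_root(lambda x: x - a, 2.0, 3.0) == pytest.approx(a)

    def test_endpoint_roots(self):
        assert bq.solve_bracketed_root(lambda x: x - 2.0, 2.0, 3.0) == 2.0
        assert bq.solve_bracketed_root(lambda x: x - 3.0, 2.0, 3.0) == 3.0

    def test_no_sign_change_raises(self):
        with pytest.raises(BracketError):
            bq.solve_bracketed_root(lambda x: x * x + 1, -1.0, 1.0)

    def test_agrees_with_pure_bisection_on_competition_equation(self):
        c_P, c_L, c_Lp, K_D, K_Dp = 1e-6, 5e-6, 1e-4, 1e-7, 2e-5
        g = lambda P: P * (1 + c_L / (K_D + P) + c_Lp / (K_Dp + P)) - c_P
        ours = bq.solve_bracketed_root(g, 0.0, c_P)
        ref = pure_bisection(g, 0.0, c_P, steps=64)
        assert ours == pytest.approx(ref, rel=1e-9)


class TestStability:
    """Extreme but allowed inputs must give finite non-negative states."""

    @pytest.mark.parametrize("K_D", [1e-18, 1e-12, 1e-3])
    @pytest.mark.parametrize("c", [1e-9, 1.0, 1e3])
    def test_extreme_ranges(self, K_D, c):
        for state in (
            bq.solve_homodimer(bq.HomodimerSpec(c, K_D)),
            bq.solve_ligand_binding(bq.LigandBindingSpec(c, c, K_D)),
            bq.solve_competing_ligands(
                bq.CompetingLigandsSpec(c, c, c, K_D, K_D * 10)
            ),
            bq.solve_competing_receptors(
                bq.CompetingReceptorsSpec(c, c, c, K_D, K_D * 10)
            ),
        ):
            for v in state.species.values():
                assert math.isfinite(v) and v >= 0
            check_conservation(state, rel=1e-8)
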