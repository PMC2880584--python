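"""AD system construction, Groebner elimination, triangular solving."""

import numpy as np
import pytest
import sympy as sp

import crnsteady as cs
from conftest import assert_point_sets_match, edelstein_cubic, multistart_positive_roots
from crnsteady.steady_state import (
    SolveError,
    SteadyStateSystem,
    TriangularBasis,
    build_ad_system,
    groebner_elimination,
    residual_check,
    solve_triangular,
)


class TestBuildAdSystem:
    def test_edelstein_equations_and_order(self, edelstein):
        """AD = {RD.v} u {B + C - et}; eliminated species sorted, retained last."""
        et = sp.Symbol("et", positive=True)
        k = {f"k{i}": sp.Symbol(f"k{i}", positive=True) for i in range(1, 7)}
        sysad = build_ad_system(edelstein.network, k, cs.CompatibilityClass([et]), "A")
        A, B, C = sp.symbols("A B C", positive=True)
        k1, k2, k3, k4, k5, k6 = (k[f"k{i}"] for i in range(1, 7))
        expected = [
            k1 * A - k2 * A**2 - k5 * C + k6 * B,
            k3 * A * B - (k4 + k5) * C + k6 * B,
            B + C - et,
        ]
        assert len(sysad.equations) == 3
        for got, want in zip(sysad.equations, expected):
            assert sp.expand(got - want) == 0
        assert [s.name for s in sysad.variables] == ["B", "C", "A"]

    def test_apoptosis_equation_count(self, apoptosis):
        sysad = build_ad_system(apoptosis.network, apoptosis.parameters, ["550"], "x4")
        assert len(sysad.equations) == 7  # rank 6 + one conservation law

    def test_full_rank_network_is_rd_v_only(self):
        net = cs.parse_network("0 -> X ; ks\nX -> 0 ; kd")
        sysad = build_ad_system(net, {"ks": 2, "kd": 1}, None, "X")
        assert len(sysad.equations) == 1

    def test_unknown_retained_species(self, edelstein):
        with pytest.raises(ValueError, match="retained"):
            build_ad_system(edelstein.network, edelstein.parameters, ["20"], "Z")


class TestGroebnerElimination:
    def test_edelstein_first_element_degree_three(self, edelstein_basis):
        """Generic Edelstein elimination leaves a cubic in the reporter."""
        A = sp.Symbol("A", positive=True)
        et = sp.Symbol("et", positive=True)
        first = edelstein_basis.first_element
        assert first.free_symbols <= {A, et}
        assert sp.Poly(first, A).degree() == 3

    def test_already_triangular_linear_system(self):
        x1, x2 = sp.symbols("x1 x2")
        G = sp.groebner([x1 - 1, x2 - x1], x2, x1, order="lex")
        assert set(G.exprs) == {x1 - 1, x2 - 1}

    def test_ideal_membership_collapse(self):
        x1 = sp.Symbol("x1")
        G = sp.groebner([x1**2 - 1, x1 - 1], x1, order="lex")
        assert list(G.exprs) == [x1 - 1]

    def test_input_polynomials_reduce_to_zero(self, edelstein_basis):
        """Every AD polynomial lies in the ideal generated by the basis."""
        for eq in edelstein_basis.system.equations:
            assert sp.expand(edelstein_basis.reduce(eq)) == 0

    def test_echelon_shape(self, apoptosis_basis):
        """Successive basis elements introduce at most one new variable."""
        varset = set(apoptosis_basis.variables)
        known = set(apoptosis_basis.retained)
        for p in apoptosis_basis.polynomials:
            new = (p.free_symbols & varset) - known
            assert len(new) <= 1
            known |= new

    def test_inconsistent_system_reports_no_steady_state(self, edelstein):
        x, y = sp.symbols("x y", positive=True)
        sysad = build_ad_system(edelstein.network, edelstein.parameters, ["20"], "A")
        fake = SteadyStateSystem(
            network=sysad.network,
            rates=sysad.rates,
            analysis=sysad.analysis,
            compatibility=sysad.compatibility,
            equations=[x + y - 1, x + y - 2],
            variables=[x, y],
            retained=[y],
        )
        basis = groebner_elimination(fake)
        assert basis.is_inconsistent
        assert solve_triangular(basis) == []
        with pytest.raises(SolveError, match="no steady state"):
            basis.first_element

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_derived_cubic(self, edelstein, seed):
        """Elimination reproduces the closed-form cubic up to a nonzero scalar."""
        rng = np.random.default_rng(seed)
        k = {f"k{i}": sp.Rational(round(10 ** rng.uniform(-1, 1), 3)) for i in range(1, 7)}
        et = sp.Symbol("et", positive=True)
        A = sp.Symbol("A", positive=True)
        sysad = build_ad_system(edelstein.network, k, cs.CompatibilityClass([et]), "A")
        first = groebner_elimination(sysad).first_element
        oracle = edelstein_cubic(k, A, et)
        q = sp.simplify(first / oracle)
        assert q.free_symbols == set() and q != 0


class TestSolveTriangular:
    def test_isomerization_unique_point(self, iso_net):
        """A <-> B with total T has exactly one steady state, in closed form."""
        k = {"k1": sp.Rational(3), "k2": sp.Rational(1)}
        sysad = build_ad_system(iso_net, k, ["8"], "B")
        pts = solve_triangular(groebner_elimination(sysad))
        assert len(pts) == 1
        # A* = k2 T / (k1 + k2), B* = k1 T / (k1 + k2)
        np.testing.assert_allclose(pts[0]["A"], 2.0, rtol=1e-12)
        np.testing.assert_allclose(pts[0]["B"], 6.0, rtol=1e-12)

    def test_edelstein_count_inside_and_outside_window(self, edelstein, edelstein_basis):
        lo, hi = edelstein.known_properties["window"]["approx_interval"]
        inside = 0.5 * (lo + hi)
        assert len(solve_triangular(edelstein_basis, {"et": inside})) == 3
        assert len(solve_triangular(edelstein_basis, {"et": 10 * hi})) == 1

    def test_points_satisfy_conservation_and_residual(self, edelstein_basis, edelstein):
        pts = solve_triangular(edelstein_basis, {"et": 20})
        for p in pts:
            assert p.residual < 1e-9
            np.testing.assert_allclose(p["B"] + p["C"], 20.0, rtol=1e-9)
            assert all(c > 0 for c in p.concentrations)

    def test_agrees_with_multistart_rootfinding_edelstein(self, edelstein, edelstein_basis):
        """Positive solutions of the un-reduced {N.v=0} u {conservation}
        match the Groebner route (rank preservation, numerically)."""
        pts = solve_triangular(edelstein_basis, {"et": 20})
        roots = multistart_positive_roots(
            edelstein.network, edelstein.parameters, [20.0], n_starts=250, seed=3
        )
        assert_point_sets_match(pts, roots, scale=20.0)

    def test_agrees_with_multistart_rootfinding_apoptosis(self, apoptosis, apoptosis_basis):
        pts = solve_triangular(apoptosis_basis, {"et": 550})
        roots = multistart_positive_roots(
            apoptosis.network, apoptosis.parameters, [550.0], n_starts=350, seed=5
        )
        assert_point_sets_match(pts, roots, scale=550.0)


class TestResidualCheck:
    def test_origin_is_equilibrium_of_closed_network(self, edelstein):
        k = {l: float(v) for l, v in edelstein.parameters.values.items()}
        assert residual_check(edelstein.network, k, [0.0, 0.0, 0.0]) == 0.0

    def test_residual_grows_linearly_under_perturbation(self, edelstein, edelstein_basis):
        (pt,) = solve_triangular(edelstein_basis, {"et": 100})
        k = {l: float(v) for l, v in edelstein.parameters.values.items()}
        x = np.asarray(pt.concentrations)
        base = residual_check(edelstein.network, k, x)
        deltas = np.array([1e-6, 1e-5, 1e-4])
        res = np.array(
            [residual_check(edelstein.network, k, x + d * np.array([1.0, -1.0, 1.0]))
             for d in deltas]
        )
        ratios = (res - base) / deltas
        # linear growth: the finite-difference slope is delta-independent
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-2)
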