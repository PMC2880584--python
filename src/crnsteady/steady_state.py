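"""Steady-state polynomial system and lexicographic Groebner elimination.

Steady states of dx/dt = N*v(k,x) inside one stoichiometric
compatibility class solve the augmented polynomial system

    AD = { rows of RD * v(k,x) }  union  { w.x - T  per conservation law }

where RD is the reduced row echelon form of N (its rows span the same
equation set as N*v = 0, without redundancy) and the affine equations
pin the class.  AD has exactly s equations in s species concentrations.

A Groebner basis of AD under lexicographic order with the retained
(reporter) species last eliminates the other variables: the basis is
echelon-shaped, its first element is a univariate polynomial in the
retained species (coefficients may contain symbolic parameters such as
a conserved total), and the remaining states are recovered by
back-substitution through the echelon.  Non-real and non-positive
branches are discarded; interior steady states are returned with an
independently evaluated residual of N*v.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .conservation import (
    CompatibilityClass,
    ConservationAnalysis,
    analyze_network,
    conservation_equations,
)
from .kinetics import RateConstants, rate_vector, species_symbols, to_rational
from .network import ReactionNetwork

__all__ = [
    "SteadyStateSystem",
    "TriangularBasis",
    "SteadyStatePoint",
    "build_ad_system",
    "groebner_elimination",
    "solve_triangular",
    "residual_check",
]

#: a root is treated as positive if it exceeds this fraction of the
#: largest compatibility-class total (guards against solver noise at 0)
POSITIVE_REL_TOL = 1e-10
#: a complex root counts as real when |imag| is below this fraction of |root|
IMAG_REL_TOL = 1e-9
#: steady-state residual bound, relative to the largest reaction rate
RESIDUAL_REL_TOL = 1e-9


class SolveError(RuntimeError):
    """Back-substitution or root-finding failure on a degenerate system."""


@dataclass
class SteadyStateSystem:
    """The AD polynomial system together with its elimination order."""

    network: ReactionNetwork
    rates: RateConstants | dict | None
    analysis: ConservationAnalysis
    compatibility: CompatibilityClass
    equations: list[sp.Expr]
    variables: list[sp.Symbol]  # eliminated first ... retained last
    retained: list[sp.Symbol]

    @property
    def parameters(self) -> set[sp.Symbol]:
        """Free symbols that are not species variables (totals, symbolic rates)."""
        free: set[sp.Symbol] = set()
        for e in self.equations:
            free |= e.free_symbols
        return free - set(self.variables)


@dataclass
class TriangularBasis:
    """Lex Groebner basis of an AD system, arranged in echelon order.

    ``polynomials[0]`` (:attr:`first_element`) involves only the retained
    variable(s) and parameters; each later polynomial introduces at most
    one new eliminated variable, so the system solves by
    back-substitution.
    """

    system: SteadyStateSystem
    polynomials: list[sp.Expr]
    variables: list[sp.Symbol]
    retained: list[sp.Symbol]
    _groebner: sp.polys.polytools.GroebnerBasis | None = field(default=None, repr=False)

    @property
    def is_inconsistent(self) -> bool:
        """True when the basis is {1}: no steady state in this class."""
        return len(self.polynomials) == 1 and self.polynomials[0].is_number

    @property
    def first_element(self) -> sp.Expr:
        if self.is_inconsistent:
            raise SolveError("inconsistent system: no steady state in this class")
        return self.polynomials[0]

    def reduce(self, expr: sp.Expr) -> sp.Expr:
        """Normal form of ``expr`` modulo the basis (0 iff in the ideal)."""
        if self._groebner is not None:
            return self._groebner.reduce(expr)[1]
        _, rem = sp.reduced(expr, self.polynomials, *self.variables, order="lex")
        return rem


@dataclass
class SteadyStatePoint:
    """One interior (all-positive) steady state, with its verification data."""

    species: list[str]
    concentrations: tuple[float, ...]
    residual: float
    class_totals: tuple[float, ...]
    interior: bool = True

    def __getitem__(self, name: str) -> float:
        return self.concentrations[self.species.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, self.concentrations))


def build_ad_system(
    net: ReactionNetwork,
    rates: RateConstants | dict | None,
    cls: CompatibilityClass | list | None,
    retained: str | list[str],
    analysis: ConservationAnalysis | None = None,
) -> SteadyStateSystem:
    """Assemble the AD system and the elimination order.

    ``retained`` names the reporter species expressed first by the
    basis; the remaining species are eliminated in alphabetical order.
    ``cls`` supplies one total per conservation law (numbers, or sympy
    symbols for parametric elimination); pass None for full-rank
    networks.
    """
    if analysis is None:
        analysis = analyze_network(net)
    if isinstance(retained, str):
        retained = [retained]
    for name in retained:
        if name not in net.species:
            raise ValueError(f"retained species {name!r} not in network {net.species}")
    if cls is None:
        cls = CompatibilityClass([])
    elif not isinstance(cls, CompatibilityClass):
        cls = CompatibilityClass(list(cls))

    v = sp.Matrix(rate_vector(net, rates))
    equations = list(analysis.RD * v) + conservation_equations(analysis, cls)

    x = species_symbols(net)
    by_name = dict(zip(net.species, x))
    retained_syms = [by_name[n] for n in retained]
    eliminated = sorted(
        (s for n, s in by_name.items() if n not in retained), key=lambda s: s.name
    )
    variables = eliminated + retained_syms
    return SteadyStateSystem(
        network=net,
        rates=rates,
        analysis=analysis,
        compatibility=cls,
        equations=equations,
        variables=variables,
        retained=retained_syms,
    )


def _echelon_order(
    polys: list[sp.Expr], variables: list[sp.Symbol], retained: list[sp.Symbol]
) -> list[sp.Expr]:
    """Order basis polynomials so each introduces at most one new variable."""
    known = set(retained)
    varset = set(variables)
    remaining = list(polys)
    ordered: list[sp.Expr] = []
    # polynomials purely in the retained block come first (univariate last var first)
    while remaining:
        best = None
        for p in remaining:
            new = (p.free_symbols & varset) - known
            if len(new) <= 1:
                if best is None or len(new) < len(best[1]):
                    best = (p, new)
                    if not new:
                        break
        if best is None:
            # cannot triangularize further; append the rest as-is
            ordered.extend(remaining)
            return ordered
        p, new = best
        remaining.remove(p)
        ordered.append(p)
        known |= new
    return ordered


def groebner_elimination(sys: SteadyStateSystem) -> TriangularBasis:
    """Lex Groebner basis of AD with the retained species eliminated last.

    Symbolic parameters (conserved totals, a scanned rate constant) stay
    in the coefficient field, so a single elimination serves a whole
    parameter scan.  An inconsistent system yields the basis {1},
    exposed via :attr:`TriangularBasis.is_inconsistent`.
    """
    G = sp.groebner(sys.equations, *sys.variables, order="lex")
    exprs = list(G.exprs)
    if exprs == [sp.Integer(1)] or exprs == [1]:
        return TriangularBasis(sys, [sp.Integer(1)], sys.variables, sys.retained, G)

    varset = set(sys.variables)
    retained_set = set(sys.retained)
    # sanity: at least one basis element must live in the retained block
    in_block = [p for p in exprs if (p.free_symbols & varset) <= retained_set]
    if not in_block:
        raise SolveError(
            "elimination produced no polynomial in the retained variable(s); "
            "the steady-state variety may be positive-dimensional"
        )
    ordered = _echelon_order(exprs, sys.variables, sys.retained)
    # put the lowest-degree retained-block polynomial first
    first = min(in_block, key=lambda p: sp.total_degree(p, *retained_set))
    ordered.remove(first)
    ordered.insert(0, first)
    return TriangularBasis(sys, ordered, sys.variables, sys.retained, G)


# Numeric solving ---------------------------------------------------------


def _univariate_real_roots(expr: sp.Expr, var: sp.Symbol) -> list[float]:
    """All real roots of a univariate polynomial with numeric coefficients.

    Companion-matrix roots (numpy) with one Newton polish step; complex
    roots with tiny imaginary part are accepted as real.
    """
    p = sp.Poly(expr, var)
    coeffs = [complex(c) for c in p.all_coeffs()]
    if any(abs(c.imag) > 0 for c in coeffs):
        raise SolveError("complex coefficients in univariate solve")
    cr = [c.real for c in coeffs]
    # strip exactly-zero leading coefficients (exact rationals upstream)
    while cr and cr[0] == 0.0:
        cr = cr[1:]
    if not cr:
        raise SolveError(f"degenerate (identically zero) polynomial in {var}")
    if len(cr) == 1:
        return []  # nonzero constant: no roots
    roots = np.roots(cr)
    dp = np.polyder(np.array(cr))
    out = []
    for z in roots:
        d = np.polyval(dp, z)
        if d != 0:
            z = z - np.polyval(cr, z) / d  # one Newton step
        if abs(z.imag) <= IMAG_REL_TOL * max(1.0, abs(z)):
            out.append(float(z.real))
    return out


def _numeric_rates(sys: SteadyStateSystem, subs: dict) -> dict[str, float]:
    out = {}
    for rxn in sys.network.reactions:
        lab = rxn.rate_label
        if sys.rates is None:
            val = subs.get(sp.Symbol(lab, positive=True))
            if val is None:
                raise SolveError(f"no numeric value for symbolic rate {lab!r}")
        elif isinstance(sys.rates, RateConstants):
            val = sys.rates[lab]
        else:
            val = sys.rates[lab]
            if isinstance(val, sp.Expr) and not val.is_number:
                val = val.subs(subs)
        val = sp.sympify(val)
        if not val.is_number:
            raise SolveError(f"rate {lab!r} still symbolic after substitution")
        out[lab] = float(val)
    return out


def residual_check(net: ReactionNetwork, rates: dict, x) -> float:
    """max_i |(N*v)_i| at concentrations ``x``, by direct evaluation.

    Deliberately bypasses sympy: rates are recomputed from the reaction
    list in plain floating point, an implementation path independent of
    the Groebner solver it verifies.
    """
    xv = np.asarray(x, dtype=float)
    res = np.zeros(net.s)
    for rxn in net.reactions:
        k = float(rates[rxn.rate_label]) if not isinstance(rates, RateConstants) else float(
            rates[rxn.rate_label]
        )
        rate = k
        for i, c in enumerate(rxn.reactant.coefficients):
            if c:
                rate *= xv[i] ** c
        for i in range(net.s):
            res[i] += rate * (rxn.product.coefficients[i] - rxn.reactant.coefficients[i])
    return float(np.max(np.abs(res)))


def _max_rate(net: ReactionNetwork, rates: dict, x) -> float:
    xv = np.asarray(x, dtype=float)
    m = 0.0
    for rxn in net.reactions:
        rate = float(rates[rxn.rate_label])
        for i, c in enumerate(rxn.reactant.coefficients):
            if c:
                rate *= xv[i] ** c
        m = max(m, abs(rate))
    return m


def _polish(sys: SteadyStateSystem, subs: dict, x0: np.ndarray) -> np.ndarray:
    """A few Newton iterations on the (numeric) AD system itself."""
    eqs = [sp.expand(e.subs(subs)) for e in sys.equations]
    xs = list(species_symbols(sys.network))
    F = sp.lambdify(xs, eqs, "numpy")
    J = sp.lambdify(xs, sp.Matrix(eqs).jacobian(xs).tolist(), "numpy")
    x = x0.copy()
    for _ in range(4):
        f = np.asarray(F(*x), dtype=float)
        j = np.asarray(J(*x), dtype=float)
        try:
            step = np.linalg.lstsq(j, -f, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        x = x + step
        if np.max(np.abs(step)) < 1e-14 * max(1.0, np.max(np.abs(x))):
            break
    return x


def solve_triangular(
    basis: TriangularBasis,
    param_subs: dict | None = None,
    include_boundary: bool = False,
    residual_rel_tol: float = RESIDUAL_REL_TOL,
) -> list[SteadyStatePoint]:
    """All positive real steady states by echelon back-substitution.

    ``param_subs`` maps parameter names (or symbols) to numbers; after
    substitution every coefficient must be numeric.  Roots of the first
    element are filtered for positivity, each surviving branch is
    back-substituted through the echelon, branches with a non-real or
    non-positive coordinate are discarded, candidates get a Newton
    polish on the AD system, and every returned point passes the
    independent residual check.

    With ``include_boundary`` the boundary (some-coordinate-zero)
    equilibria found along the way are returned too, flagged
    ``interior=False``; they are never part of the default output
    because compatibility-class multistationarity concerns interior
    states.
    """
    sys = basis.system
    if basis.is_inconsistent:
        return []
    # normalize substitution keys to the actual symbols, values to exact rationals
    subs: dict[sp.Symbol, sp.Rational] = {}
    if param_subs:
        by_name = {s.name: s for s in sys.parameters}
        for key, val in param_subs.items():
            sym = by_name.get(key.name if isinstance(key, sp.Symbol) else str(key))
            if sym is None:
                continue
            subs[sym] = to_rational(val)
    leftover = sys.parameters - set(subs)
    if leftover:
        raise SolveError(
            f"parameters {sorted(s.name for s in leftover)} need numeric values"
        )

    totals_num = tuple(
        float(sp.sympify(t).subs(subs)) for t in sys.compatibility.totals
    )
    scale = max([1.0, *[abs(t) for t in totals_num]])
    pos_tol = POSITIVE_REL_TOL * scale

    polys = [sp.expand(p.subs(subs)) for p in basis.polynomials]
    varset = set(sys.variables)

    partials: list[dict[sp.Symbol, float]] = [{}]
    for p in polys:
        if not (p.free_symbols & varset):
            continue
        next_partials: list[dict[sp.Symbol, float]] = []
        for assign in partials:
            pe = p.subs(assign)
            unknowns = pe.free_symbols & varset
            if not unknowns:
                next_partials.append(assign)  # consistency enforced by residual later
                continue
            if len(unknowns) > 1:
                next_partials.append(assign)  # a later echelon poly will pin these
                continue
            (var,) = unknowns
            try:
                roots = _univariate_real_roots(pe, var)
            except SolveError:
                continue
            for r in roots:
                if r < -pos_tol:
                    continue  # negative branch: not a concentration
                na = dict(assign)
                na[var] = r
                next_partials.append(na)
        partials = next_partials
        if not partials:
            return []

    xs = list(species_symbols(sys.network))
    nrates = _numeric_rates(sys, subs)
    points: list[SteadyStatePoint] = []
    seen: list[np.ndarray] = []
    for assign in partials:
        if set(xs) - set(assign):
            continue  # under-determined branch (degenerate); skip
        x0 = np.array([assign[s] for s in xs], dtype=float)
        x0 = _polish(sys, subs, x0)
        if not np.all(np.isfinite(x0)):
            continue
        if np.any(x0 < -pos_tol):
            continue
        res = residual_check(sys.network, nrates, x0)
        tol = residual_rel_tol * max(1.0, _max_rate(sys.network, nrates, x0))
        if res > tol:
            continue
        if any(np.allclose(x0, q, rtol=1e-7, atol=1e-9 * scale) for q in seen):
            continue
        seen.append(x0)
        interior = bool(np.all(x0 > pos_tol))
        if not interior and not include_boundary:
            continue
        points.append(
            SteadyStatePoint(
                species=list(sys.network.species),
                concentrations=tuple(float(v) for v in x0),
                residual=res,
                class_totals=totals_num,
                interior=interior,
            )
        )
    points.sort(key=lambda p: p.concentrations)
    return points
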