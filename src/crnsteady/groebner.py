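"""Textbook Buchberger algorithm, kept small as an independent oracle.

This is deliberately the naive algorithm — S-polynomials, full
multivariate division, pairwise completion, then inter-reduction to the
unique reduced monic basis — restricted to tiny systems (<= 3 variables,
total degree <= 4, rational coefficients).  It exists to cross-validate
the production elimination path (sympy's Groebner engine) on small
random systems and on the Edelstein AD system at numeric parameters;
it is never used to solve anything.
"""

from __future__ import annotations

import itertools

import sympy as sp
from sympy.polys.orderings import lex

__all__ = ["buchberger_oracle", "OracleScopeError", "reduced_basis_set"]

MAX_VARS = 3
MAX_DEGREE = 4


class OracleScopeError(ValueError):
    """Input outside the oracle's deliberately small validated scope."""


def _lm(p: sp.Poly) -> tuple[int, ...]:
    return p.monoms(order=lex)[0]


def _lc(p: sp.Poly):
    return p.coeffs(order=lex)[0]


def _mono_lcm(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(max(x, y) for x, y in zip(a, b))


def _mono_div(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...] | None:
    d = tuple(x - y for x, y in zip(a, b))
    return d if all(e >= 0 for e in d) else None


def _term(gens, mono, coeff) -> sp.Poly:
    e = coeff
    for g, m in zip(gens, mono):
        e *= g**m
    return sp.Poly(e, *gens, domain="QQ")


def _divide(f: sp.Poly, G: list[sp.Poly], gens) -> sp.Poly:
    """Full multivariate division: remainder of f modulo G (lex)."""
    r = sp.Poly(0, *gens, domain="QQ")
    p = f
    while not p.is_zero:
        lm_p, lc_p = _lm(p), _lc(p)
        for g in G:
            q = _mono_div(lm_p, _lm(g))
            if q is not None:
                p = p - _term(gens, q, lc_p / _lc(g)) * g
                break
        else:
            t = _term(gens, lm_p, lc_p)
            r = r + t
            p = p - t
    return r


def _s_poly(f: sp.Poly, g: sp.Poly, gens) -> sp.Poly:
    l = _mono_lcm(_lm(f), _lm(g))
    tf = _term(gens, _mono_div(l, _lm(f)), sp.Rational(1) / _lc(f))
    tg = _term(gens, _mono_div(l, _lm(g)), sp.Rational(1) / _lc(g))
    return tf * f - tg * g


def buchberger_oracle(polys, gens, max_vars: int = MAX_VARS, max_degree: int = MAX_DEGREE):
    """Reduced monic lex Groebner basis by naive Buchberger completion.

    Refuses systems beyond its validated scope (too many variables, too
    high degree, non-rational coefficients) — the oracle is for tests.
    Returns sympy expressions sorted by descending lex leading monomial,
    the same normal form the production path is compared against.
    """
    gens = tuple(gens)
    if len(gens) > max_vars:
        raise OracleScopeError(f"oracle handles <= {max_vars} variables, got {len(gens)}")
    G: list[sp.Poly] = []
    for p in polys:
        extra = set(sp.sympify(p).free_symbols) - set(gens)
        if extra:
            raise OracleScopeError(f"symbols {extra} outside the generator list")
        try:
            q = sp.Poly(sp.expand(p), *gens, domain="QQ")
        except sp.polys.polyerrors.CoercionFailed as exc:
            raise OracleScopeError(f"non-rational coefficients in {p}") from exc
        if q.total_degree() > max_degree:
            raise OracleScopeError(
                f"oracle handles total degree <= {max_degree}, got {q.total_degree()}"
            )
        if not q.is_zero:
            G.append(q)
    if not G:
        return [sp.Integer(0)]

    pairs = set(itertools.combinations(range(len(G)), 2))
    while pairs:
        i, j = pairs.pop()
        fi, fj = G[i], G[j]
        # Buchberger's first criterion: coprime leading monomials
        if _mono_lcm(_lm(fi), _lm(fj)) == tuple(a + b for a, b in zip(_lm(fi), _lm(fj))):
            continue
        r = _divide(_s_poly(fi, fj, gens), G, gens)
        if not r.is_zero:
            G.append(r)
            pairs |= {(t, len(G) - 1) for t in range(len(G) - 1)}

    # minimalize: drop polys whose leading monomial another's divides
    minimal: list[sp.Poly] = []
    for i, g in enumerate(G):
        if any(
            _mono_div(_lm(g), _lm(h)) is not None
            for j, h in enumerate(G)
            if j != i and (j < i or _lm(h) != _lm(g))
        ):
            continue
        minimal.append(g)
    # fully reduce each element against the others, make monic
    reduced: list[sp.Poly] = []
    for i, g in enumerate(minimal):
        others = minimal[:i] + minimal[i + 1 :]
        r = _divide(g, others, gens) if others else g
        if not r.is_zero:
            reduced.append(r.monic())
    reduced.sort(key=lambda p: _lm(p), reverse=True)
    if any(p.is_one for p in reduced):
        return [sp.Integer(1)]
    return [p.as_expr() for p in reduced]


def reduced_basis_set(exprs, gens) -> set[sp.Expr]:
    """Monic, expanded normal form of a basis for set comparison."""
    out = set()
    for e in exprs:
        p = sp.Poly(sp.expand(e), *gens, domain="QQ").monic()
        out.add(sp.expand(p.as_expr()))
    return out
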