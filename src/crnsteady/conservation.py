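"""Exact linear algebra on the stoichiometric matrix.

Conserved moieties are left-null vectors w of N: w.x(t) is constant
along every trajectory because w.(dx/dt) = (w.N).v = 0.  With rho =
rank(N) there are exactly s - rho independent conservation relations,
and trajectories live in parallel translates (stoichiometric
compatibility classes) of the stoichiometric subspace T = span of the
reaction vectors.

Everything here is exact fraction arithmetic — no pivot tolerances.
The conservation relations feed the steady-state polynomial system,
which must be exactly consistent for Groebner elimination to behave.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import sympy as sp

from .kinetics import species_symbols, to_rational
from .network import ReactionNetwork

__all__ = [
    "ConservationAnalysis",
    "CompatibilityClass",
    "rref",
    "left_nullspace",
    "analyze_network",
    "conservation_equations",
]


def rref(M: sp.Matrix) -> tuple[sp.Matrix, tuple[int, ...]]:
    """Reduced row echelon form with zero rows dropped.

    Returns (RD, pivot column indices); RD has rank(M) rows, each pivot
    entry 1 with zeros above and below.  Exact rational arithmetic.
    """
    R, pivots = sp.Matrix(M).rref()
    RD = R[: len(pivots), :]
    return RD, tuple(pivots)


def _normalize_integer(vec: sp.Matrix) -> sp.Matrix:
    """Scale a rational vector to coprime integers with positive leading entry."""
    denoms = [sp.Rational(e).q for e in vec]
    v = [int(e * sp.ilcm(*denoms)) if len(denoms) > 1 else int(e * denoms[0]) for e in vec]
    g = 0
    for e in v:
        g = gcd(g, abs(e))
    if g > 1:
        v = [e // g for e in v]
    lead = next((e for e in v if e != 0), 1)
    if lead < 0:
        v = [-e for e in v]
    return sp.Matrix(v)


def left_nullspace(N: sp.Matrix) -> list[sp.Matrix]:
    """Integer-normalized basis of {w : w^T N = 0}.

    Each vector is scaled to integer entries with gcd 1 and positive
    first nonzero entry, so output is reproducible across runs.
    """
    return [_normalize_integer(w) for w in sp.Matrix(N).T.nullspace()]


@dataclass
class ConservationAnalysis:
    """Rank, RREF rows, conservation vectors, and a basis of T for one network."""

    network: ReactionNetwork
    rank: int
    RD: sp.Matrix
    pivots: tuple[int, ...]
    conservation_vectors: list[sp.Matrix]
    subspace_basis: sp.Matrix  # s x rho, columns span the stoichiometric subspace

    @property
    def n_conserved(self) -> int:
        return len(self.conservation_vectors)


def analyze_network(net: ReactionNetwork) -> ConservationAnalysis:
    """Full conservation analysis of a network (exact)."""
    N = net.stoichiometric_matrix()
    RD, pivots = rref(N)
    vectors = left_nullspace(N)
    basis = N[:, list(pivots)] if pivots else sp.zeros(net.s, 0)
    return ConservationAnalysis(
        network=net,
        rank=len(pivots),
        RD=RD,
        pivots=pivots,
        conservation_vectors=vectors,
        subspace_basis=basis,
    )


@dataclass
class CompatibilityClass:
    """Totals T_i (one per conservation vector) fixing a compatibility class."""

    totals: list

    def __post_init__(self):
        vals = []
        for t in self.totals:
            if isinstance(t, sp.Expr) and not t.is_number:
                vals.append(t)  # symbolic total, e.g. a scanned parameter
                continue
            r = to_rational(t)
            if r <= 0:
                raise ValueError(f"compatibility-class totals must be positive, got {t}")
            vals.append(r)
        self.totals = vals


def conservation_equations(
    analysis: ConservationAnalysis, cls: CompatibilityClass
) -> list[sp.Expr]:
    """Affine polynomials w.x - T, one per conservation vector.

    Their zero sets cut the compatibility class out of concentration
    space; appended to the reduced steady-state equations they make the
    polynomial system zero-dimensional for generic parameters.
    """
    vectors = analysis.conservation_vectors
    if len(cls.totals) != len(vectors):
        raise ValueError(
            f"need {len(vectors)} total(s) (one per conservation vector), "
            f"got {len(cls.totals)}"
        )
    x = species_symbols(analysis.network)
    eqs = []
    for w, T in zip(vectors, cls.totals):
        eqs.append(sum(int(wi) * xi for wi, xi in zip(w, x)) - T)
    return eqs
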