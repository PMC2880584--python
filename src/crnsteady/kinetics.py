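"""Mass-action kinetics: symbolic rate vector, ODE right-hand side, Jacobian.

Under mass action the rate of reaction j is the rate constant k_j times
the product of reactant concentrations raised to their stoichiometric
coefficients:  v_j = k_j * prod_i x_i^(y_i)  where y is the reactant
complex of reaction j.  The ODE system is dx/dt = N*v(k, x); it factors
as Y*Ia*K*Phi(x) where K places k_j in the reactant-complex column and
Phi is the vector of complex monomials.  The factored form is kept as a
cross-check constructor; N*v is the production path.

Rate constants supplied as int/str/Fraction-like values are converted to
exact sympy Rationals (floats go through their shortest decimal string,
so 0.1 becomes 1/10).  Exact coefficients matter: the downstream
Groebner computations are fragile under floating-point coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Real

import sympy as sp

from .network import ReactionNetwork

__all__ = [
    "RateConstants",
    "MassActionSystem",
    "rate_vector",
    "ode_rhs",
    "jacobian",
    "species_symbols",
    "to_rational",
]


def to_rational(value) -> sp.Rational:
    """Exact rational from int, float, str ('0.25', '1/4') or sympy number."""
    if isinstance(value, sp.Expr):
        return sp.nsimplify(value, rational=True)
    if isinstance(value, float):
        return sp.Rational(repr(value))
    return sp.Rational(value)


@dataclass
class RateConstants:
    """Positive rate-constant values keyed by label.

    Units follow mass action: (1/time) * (concentration)^(1-order) for a
    reaction of the given reactant molecularity.
    """

    values: dict[str, sp.Rational] = field(default_factory=dict)

    def __post_init__(self):
        conv = {}
        for label, v in self.values.items():
            r = to_rational(v)
            if r <= 0:
                raise ValueError(f"rate constant {label!r} must be positive, got {v}")
            conv[label] = r
        self.values = conv

    def __getitem__(self, label: str) -> sp.Rational:
        return self.values[label]

    def __contains__(self, label: str) -> bool:
        return label in self.values

    def require(self, labels: list[str]) -> None:
        missing = [l for l in labels if l not in self.values]
        if missing:
            raise KeyError(f"missing rate constants for reactions: {', '.join(missing)}")


def species_symbols(net: ReactionNetwork) -> tuple[sp.Symbol, ...]:
    """One positive sympy symbol per species, in species order."""
    return tuple(sp.Symbol(name, positive=True) for name in net.species)


def _rate_symbols(net: ReactionNetwork) -> dict[str, sp.Symbol]:
    return {lab: sp.Symbol(lab, positive=True) for lab in net.rate_labels}


def rate_vector(net: ReactionNetwork, rates: RateConstants | dict | None = None) -> list[sp.Expr]:
    """Mass-action rate monomials, one per reaction, in reaction order.

    ``rates`` may be numeric (:class:`RateConstants` or a plain dict), or
    None to keep every constant symbolic.  A dict may also mix numbers
    with sympy expressions (used to leave one constant symbolic during a
    scan).
    """
    x = species_symbols(net)
    if rates is None:
        kmap: dict[str, sp.Expr] = dict(_rate_symbols(net))
    elif isinstance(rates, RateConstants):
        rates.require(net.rate_labels)
        kmap = dict(rates.values)
    else:
        kmap = {}
        for lab in net.rate_labels:
            if lab not in rates:
                raise KeyError(f"missing rate constant for reaction {lab!r}")
            v = rates[lab]
            kmap[lab] = v if isinstance(v, sp.Expr) else to_rational(v)
    v = []
    for rxn in net.reactions:
        mono = sp.Integer(1)
        for xi, c in zip(x, rxn.reactant.coefficients):
            if c:
                mono *= xi**c
        v.append(kmap[rxn.rate_label] * mono)
    return v


def _complex_monomials(net: ReactionNetwork) -> list[sp.Expr]:
    x = species_symbols(net)
    out = []
    for cv in net.complexes:
        mono = sp.Integer(1)
        for xi, c in zip(x, cv.coefficients):
            if c:
                mono *= xi**c
        out.append(mono)
    return out


class MassActionSystem:
    """A reaction network endowed with mass-action kinetics.

    Attributes
    ----------
    network : ReactionNetwork
    x : tuple of sympy symbols, one per species
    v : list of rate monomials (reaction order)
    rhs : list of ODE right-hand sides N*v (species order)
    """

    def __init__(self, network: ReactionNetwork, rates: RateConstants | dict | None = None):
        self.network = network
        self.rates = rates
        self.x = species_symbols(network)
        self.v = rate_vector(network, rates)
        N = network.stoichiometric_matrix()
        self.rhs = list(N * sp.Matrix(self.v))

    def jacobian(self) -> sp.Matrix:
        """s x s matrix of partial derivatives d(rhs_i)/d(x_j)."""
        return sp.Matrix(self.rhs).jacobian(self.x)

    def rhs_kphi(self) -> list[sp.Expr]:
        """Right-hand side built the factored way, Y*Ia*K*Phi(x).

        K is r x c with k_j in row j at the reactant-complex column.
        Symbolically identical to ``self.rhs``; kept as an independent
        construction for cross-checking.
        """
        net = self.network
        if self.rates is None:
            kmap: dict[str, sp.Expr] = dict(_rate_symbols(net))
        elif isinstance(self.rates, RateConstants):
            kmap = dict(self.rates.values)
        else:
            kmap = {
                lab: (v if isinstance(v, sp.Expr) else to_rational(v))
                for lab, v in self.rates.items()
            }
        K = sp.zeros(net.r, net.c)
        for j, rxn in enumerate(net.reactions):
            K[j, net.complex_index(rxn.reactant)] = kmap[rxn.rate_label]
        Phi = sp.Matrix(_complex_monomials(net))
        Y = net.complex_matrix()
        Ia = net.incidence_matrix()
        return list(Y * Ia * K * Phi)

    def evaluate_rhs(self, point) -> list[float]:
        """Numeric rhs at a concentration vector (requires numeric rates)."""
        subs = dict(zip(self.x, point))
        return [float(e.subs(subs)) for e in self.rhs]


def ode_rhs(system: MassActionSystem) -> list[sp.Expr]:
    return list(system.rhs)


def jacobian(system: MassActionSystem) -> sp.Matrix:
    return system.jacobian()
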