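"""Bundled example networks, a random-network generator, and a seeded
search for multistationary rate-constant sets.

Two networks ship with the package:

* The Edelstein network — the classic three-species autocatalytic
  scheme (A <-> 2A, A + B <-> C, C <-> B) with one conserved moiety
  (B + C) and, for suitable rate constants, a bistable window in the
  conserved total.

* A receptor-induced apoptosis network — seven species, fourteen
  mass-action reactions: activated caspase-8 (x1 = C8*) binds and
  cleaves caspase-3 (x2 = C3, complex x3 = C8*C3, product x4 = C3*),
  while the inhibitor BAR (x5) sequesters C8* both free (x6 = C8*BAR)
  and substrate-bound (x7 = C8*C3BAR); C3 and BAR turn over, BAR
  degrades both free (rate kd) and in complex (releasing the caspase
  moiety), and active C3* is cleared.  Total C8* (x1 + x3 + x6 + x7)
  is conserved.  The published diagram for this model is not machine
  readable, so the bundled reaction list is a documented
  reconstruction satisfying every stated constraint (seven species,
  fourteen reactions, the C8* conservation law, BAR degradation
  governed by kd); it is labelled as such, not as the original.

Shipped rate-constant sets are the output of
:func:`bistable_parameter_search` with the seed recorded in the
parameter file; they are found by the search, not taken from any
publication.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import sympy as sp
import yaml

from .conservation import CompatibilityClass, analyze_network
from .kinetics import RateConstants, to_rational
from .network import ComplexVector, Reaction, ReactionNetwork, parse_network
from .steady_state import build_ad_system, groebner_elimination, solve_triangular

__all__ = [
    "FixtureRecord",
    "SearchResult",
    "edelstein_network",
    "apoptosis_network",
    "random_network",
    "bistable_parameter_search",
    "load_parameter_file",
]


@dataclass
class FixtureRecord:
    network: ReactionNetwork
    parameters: RateConstants | None
    known_properties: dict


def _data_text(name: str) -> str:
    return (resources.files("crnsteady") / "data" / name).read_text()


def load_parameter_file(text: str) -> tuple[RateConstants, dict]:
    """Parse a YAML/JSON parameter file into rate constants + metadata.

    Accepts either a flat ``{label: value}`` map or a document with a
    ``rates:`` section (extra sections are returned as metadata).
    Values may be numbers or exact-fraction strings like ``"1/20"``.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("parameter file must be a mapping")
    raw = doc.get("rates", doc)
    meta = {k: v for k, v in doc.items() if k != "rates"} if "rates" in doc else {}
    rates = RateConstants({str(k): to_rational(v) for k, v in raw.items()})
    return rates, meta


def edelstein_network() -> FixtureRecord:
    """The Edelstein autocatalytic network with its stored bistable rate set."""
    net = parse_network(_data_text("edelstein.crn"), name="edelstein")
    rates, meta = load_parameter_file(_data_text("edelstein_params.yaml"))
    props = {
        "s": 3,
        "c": 5,
        "r": 6,
        "rank": 2,
        "conservation_vectors": [(0, 1, 1)],
        "retained": "A",
        **meta,
    }
    return FixtureRecord(network=net, parameters=rates, known_properties=props)


def apoptosis_network() -> FixtureRecord:
    """The reconstructed 7-species / 14-reaction apoptosis network."""
    net = parse_network(_data_text("apoptosis.crn"), name="apoptosis")
    rates, meta = load_parameter_file(_data_text("apoptosis_params.yaml"))
    props = {
        "s": 7,
        "r": 14,
        "rank": 6,
        "conservation_vectors": [(1, 0, 1, 0, 0, 1, 1)],  # total C8*
        "retained": "x4",  # cleaved caspase-3, the executioner readout
        **meta,
    }
    return FixtureRecord(network=net, parameters=rates, known_properties=props)


# Random networks --------------------------------------------------------


def _draw_complex(rng: np.random.Generator, s: int, allow_zero: bool = True) -> tuple[int, ...]:
    total = int(rng.integers(0 if allow_zero else 1, 3))
    v = [0] * s
    for _ in range(total):
        v[int(rng.integers(0, s))] += 1
    return tuple(v)


def random_network(
    s: int,
    r: int,
    seed: int,
    n_conservation: int = 0,
    max_attempts: int = 200,
) -> FixtureRecord:
    """Seeded random mass-action network with planted conservation laws.

    Complexes have total stoichiometry <= 2.  Candidate reactions are
    rejected unless every planted left-null vector w satisfies
    w.(product - reactant) = 0, so the planted vectors are guaranteed
    to lie in the left null space of N.  With ``n_conservation == 0``
    and r >= s the draw is retried until N has full rank s, so the
    generator's record of conserved relations is exact either way.
    """
    if s < 2 or r < 1 or not (0 <= n_conservation < s):
        raise ValueError("need s >= 2, r >= 1, 0 <= n_conservation < s")
    rng = np.random.default_rng(seed)
    species = [f"S{i+1}" for i in range(s)]

    for _restart in range(max_attempts):
        planted: list[tuple[int, ...]] = []
        while len(planted) < n_conservation:
            w = tuple(int(rng.integers(0, 3)) for _ in range(s))
            if all(e == 0 for e in w):
                continue
            cand = planted + [w]
            if sp.Matrix(cand).rank() == len(cand):
                planted = cand

        def weight(cv: tuple[int, ...]) -> tuple[int, ...]:
            return tuple(sum(wi * ci for wi, ci in zip(w, cv)) for w in planted)

        reactions: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
        ok = True
        for _ in range(r):
            for _try in range(max_attempts):
                yr = _draw_complex(rng, s)
                yp = _draw_complex(rng, s)
                if yp == yr:
                    continue
                if weight(yp) != weight(yr):
                    continue
                if (yr, yp) in reactions:
                    continue
                reactions.append((yr, yp))
                break
            else:
                ok = False
                break
        if not ok:
            continue

        complexes: list[ComplexVector] = []
        cset = set()
        rxns: list[Reaction] = []
        for j, (yr, yp) in enumerate(reactions):
            rc, pc = ComplexVector(yr), ComplexVector(yp)
            for cv in (rc, pc):
                if cv not in cset:
                    cset.add(cv)
                    complexes.append(cv)
            rxns.append(Reaction(rc, pc, f"k{j+1}"))
        net = ReactionNetwork(species, complexes, rxns, name=f"random_s{s}_r{r}_seed{seed}")
        rank = len(analyze_network(net).pivots)
        if n_conservation == 0 and r >= s and rank < s:
            continue  # accidental conservation; redraw
        props = {
            "s": s,
            "r": r,
            "seed": seed,
            "planted_conservation": [list(w) for w in planted],
        }
        return FixtureRecord(network=net, parameters=None, known_properties=props)
    raise RuntimeError(
        f"could not satisfy the constraints after {max_attempts} restarts "
        f"(s={s}, r={r}, n_conservation={n_conservation})"
    )


# Bistable parameter search ----------------------------------------------


@dataclass
class SearchResult:
    rates: dict[str, sp.Rational]
    witness_total: sp.Rational
    max_states: int
    draw_index: int
    seed: int


def _nice_rational(value: float, sig: int = 2) -> sp.Rational:
    """Round to ``sig`` significant digits and convert to an exact rational."""
    if value == 0:
        return sp.Rational(0)
    from decimal import Decimal

    d = Decimal(repr(value))
    shift = d.adjusted() - (sig - 1)
    q = d.scaleb(-shift).to_integral_value() * Decimal(10) ** shift
    return sp.Rational(str(q))


def bistable_parameter_search(
    net: ReactionNetwork,
    retained: str,
    seed: int,
    n_draws: int = 400,
    lo: float = 1e-2,
    hi: float = 1e2,
    total_grid: np.ndarray | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> SearchResult | None:
    """Seeded random search for a rate set with >= 3 positive steady states.

    Draws log-uniform rate constants (rounded to 2 significant digits,
    kept as exact rationals), eliminates once per draw with the first
    conserved total symbolic, and counts positive real roots of the
    retained-variable polynomial over a grid of totals by an exact
    Sturm sign count.  A draw whose count reaches 3 is confirmed by
    full back-substitution (interior steady states only) before being
    accepted.  ``ranges`` narrows the sampling box for chosen labels.
    Returns None when the budget is exhausted — which says the searched
    region looked monostationary, not that the network is.
    """
    analysis = analyze_network(net)
    if analysis.n_conserved == 0:
        raise ValueError("bistable_parameter_search needs a conservation law to scan")
    rng = np.random.default_rng(seed)
    if total_grid is None:
        total_grid = np.logspace(-2, 3, 40)
    T = sp.Symbol("et", positive=True)
    totals = [T] + [sp.Integer(1)] * (analysis.n_conserved - 1)
    ranges = ranges or {}
    labels = net.rate_labels
    xret = sp.Symbol(retained, positive=True)

    for draw in range(n_draws):
        k = {}
        for lab in labels:
            a, b = ranges.get(lab, (lo, hi))
            k[lab] = _nice_rational(10 ** rng.uniform(np.log10(a), np.log10(b)))
        sys = build_ad_system(net, k, CompatibilityClass(totals), retained, analysis)
        try:
            basis = groebner_elimination(sys)
            first = basis.first_element
        except Exception:
            continue
        hit = None
        for tv in total_grid:
            p = sp.Poly(first.subs(T, _nice_rational(float(tv), sig=6)), xret)
            if p.degree() < 3:
                break  # cannot have 3 roots at any total
            try:
                n_pos = p.count_roots(0, None)  # exact Sturm count on (0, oo)
            except sp.PolynomialError:
                continue
            if n_pos >= 3:
                hit = _nice_rational(float(tv), sig=6)
                break
        if hit is None:
            continue
        pts = solve_triangular(basis, {"et": hit})
        if len(pts) >= 3:
            return SearchResult(
                rates=k, witness_total=hit, max_states=len(pts), draw_index=draw, seed=seed
            )
    return None
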