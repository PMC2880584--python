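"""Reaction-network parsing and structural matrices.

A chemical reaction network (CRN) is three sets: species, complexes
(formal non-negative integer combinations of species appearing on either
side of a reaction arrow, including the zero complex ``0`` of open
systems), and reactions (ordered pairs of complexes with a named rate
constant).  From these we build the complex matrix Y (species x
complexes), the incidence matrix Ia (complexes x reactions, one -1/+1
pair per column) and the stoichiometric matrix N = Y*Ia whose columns
are the reaction vectors (product complex minus reactant complex).

Networks are read from a small plain-text ``.crn`` dialect::

    # comment
    species: A B C          # optional: pins species order
    A <-> 2A ; k1, k2       # reversible, forward then backward label
    A + B -> C ; k3
    0 -> C ; ks             # zero complex (synthesis / inflow)
    2 A -> A ; k2b          # "2A" and "2 A" both mean coefficient 2

All arithmetic is exact integer arithmetic (sympy matrices).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import sympy as sp

__all__ = [
    "ComplexVector",
    "Reaction",
    "ReactionNetwork",
    "CRNParseError",
    "parse_network",
    "to_crn",
    "complex_matrix",
    "incidence_matrix",
    "stoichiometric_matrix",
]


class CRNParseError(ValueError):
    """Malformed or inconsistent ``.crn`` input; carries a line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ComplexVector:
    """Stoichiometric coefficients of one complex, in species order.

    ``coefficients[i]`` is the (non-negative integer) coefficient of
    species ``i``.  The all-zero tuple is the zero complex.
    """

    coefficients: tuple[int, ...]

    def __post_init__(self):
        if any((not isinstance(c, int)) or c < 0 for c in self.coefficients):
            raise ValueError(
                f"complex coefficients must be non-negative integers, got {self.coefficients}"
            )

    @property
    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coefficients)

    @property
    def total(self) -> int:
        """Total stoichiometry (molecularity) of the complex."""
        return sum(self.coefficients)

    def format(self, species: list[str]) -> str:
        if self.is_zero:
            return "0"
        parts = []
        for name, c in zip(species, self.coefficients):
            if c == 1:
                parts.append(name)
            elif c > 1:
                parts.append(f"{c}{name}")
        return " + ".join(parts)


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction ``reactant -> product`` with rate label.

    Reversible arrows in input files are expanded into two Reaction
    records before this type is ever constructed.
    """

    reactant: ComplexVector
    product: ComplexVector
    rate_label: str

    def __post_init__(self):
        if self.reactant == self.product:
            raise ValueError(f"null reaction (reactant == product) for {self.rate_label!r}")


@dataclass
class ReactionNetwork:
    """Species, complexes and reactions with a stable ordering.

    Species order is first appearance (or the ``species:`` header);
    complexes are deduplicated in first-appearance order, reactant of a
    reversible pair before its product.  All matrix constructions use
    these orders.
    """

    species: list[str]
    complexes: list[ComplexVector]
    reactions: list[Reaction]
    name: str = ""
    _complex_index: dict[ComplexVector, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        self._complex_index = {c: i for i, c in enumerate(self.complexes)}
        if len(self._complex_index) != len(self.complexes):
            raise ValueError("complexes must be distinct")
        labels = [r.rate_label for r in self.reactions]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate rate labels: {', '.join(dup)}")
        for r in self.reactions:
            for c in (r.reactant, r.product):
                if c not in self._complex_index:
                    raise ValueError(f"reaction complex {c} missing from complex list")

    @property
    def s(self) -> int:
        return len(self.species)

    @property
    def c(self) -> int:
        return len(self.complexes)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def rate_labels(self) -> list[str]:
        return [r.rate_label for r in self.reactions]

    def complex_index(self, cv: ComplexVector) -> int:
        return self._complex_index[cv]

    # Matrices -----------------------------------------------------------

    def complex_matrix(self) -> sp.Matrix:
        """Y: species x complexes, column j is complex j."""
        return sp.Matrix(self.s, self.c, lambda i, j: self.complexes[j].coefficients[i])

    def incidence_matrix(self) -> sp.Matrix:
        """Ia: complexes x reactions, -1 at the reactant row, +1 at the product row."""
        Ia = sp.zeros(self.c, self.r)
        for j, rxn in enumerate(self.reactions):
            Ia[self._complex_index[rxn.reactant], j] = -1
            Ia[self._complex_index[rxn.product], j] = 1
        return Ia

    def stoichiometric_matrix(self) -> sp.Matrix:
        """N = Y*Ia: species x reactions, column j = product_j - reactant_j."""
        N = sp.zeros(self.s, self.r)
        for j, rxn in enumerate(self.reactions):
            for i in range(self.s):
                N[i, j] = rxn.product.coefficients[i] - rxn.reactant.coefficients[i]
        return N


# Module-level aliases matching the functional surface.

def complex_matrix(net: ReactionNetwork) -> sp.Matrix:
    return net.complex_matrix()


def incidence_matrix(net: ReactionNetwork) -> sp.Matrix:
    return net.incidence_matrix()


def stoichiometric_matrix(net: ReactionNetwork) -> sp.Matrix:
    return net.stoichiometric_matrix()


# Parsing ----------------------------------------------------------------

_TERM_RE = re.compile(r"^(\d+)?\s*([A-Za-z_][A-Za-z0-9_*']*)$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_*']*$")


def _parse_side(side: str, lineno: int) -> dict[str, int]:
    """Parse one side of an arrow into {species name: coefficient}."""
    side = side.strip()
    if side == "0":
        return {}
    coeffs: dict[str, int] = {}
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise CRNParseError("empty term in complex", lineno)
        m = _TERM_RE.match(term)
        if m is None:
            if re.match(r"^-|\.|/", term) or re.search(r"[-./]", term):
                raise CRNParseError(
                    f"invalid stoichiometric coefficient in {term!r} "
                    "(coefficients must be non-negative integers)",
                    lineno,
                )
            raise CRNParseError(f"cannot parse complex term {term!r}", lineno)
        coef = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        coeffs[name] = coeffs.get(name, 0) + coef
    return coeffs


def parse_network(text: str, name: str = "") -> ReactionNetwork:
    """Parse ``.crn`` text into a :class:`ReactionNetwork`.

    Raises :class:`CRNParseError` with a line number on malformed lines,
    duplicate rate labels, or invalid coefficients.
    """
    header_species: list[str] | None = None
    raw: list[tuple[int, dict[str, int], dict[str, int], str, list[str]]] = []
    seen_species: list[str] = []

    def note_species(d: dict[str, int]):
        for k in d:
            if k not in seen_species:
                seen_species.append(k)

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("species:"):
            if header_species is not None:
                raise CRNParseError("duplicate species: header", lineno)
            header_species = line.split(":", 1)[1].split()
            for s in header_species:
                if not _NAME_RE.match(s):
                    raise CRNParseError(f"invalid species name {s!r}", lineno)
            if len(set(header_species)) != len(header_species):
                raise CRNParseError("duplicate species in header", lineno)
            continue
        if ";" not in line:
            raise CRNParseError("missing '; rate-label' part", lineno)
        body, labels_part = line.rsplit(";", 1)
        labels = [l.strip() for l in labels_part.split(",") if l.strip()]
        if "<->" in body:
            arrow = "<->"
        elif "->" in body:
            arrow = "->"
        else:
            raise CRNParseError("missing reaction arrow '->' or '<->'", lineno)
        lhs, _, rhs = body.partition(arrow)
        reactant = _parse_side(lhs, lineno)
        product = _parse_side(rhs, lineno)
        if reactant == product:
            raise CRNParseError("null reaction: reactant equals product", lineno)
        expected = 2 if arrow == "<->" else 1
        if len(labels) != expected:
            raise CRNParseError(
                f"expected {expected} rate label(s) for {arrow!r}, got {len(labels)}", lineno
            )
        for l in labels:
            if not _NAME_RE.match(l):
                raise CRNParseError(f"invalid rate label {l!r}", lineno)
        note_species(reactant)
        note_species(product)
        if arrow == "->":
            raw.append((lineno, reactant, product, labels[0], labels))
        else:
            raw.append((lineno, reactant, product, labels[0], labels))
            raw.append((lineno, product, reactant, labels[1], labels))

    if not raw:
        raise CRNParseError("no reactions found")

    if header_species is not None:
        missing = [s for s in seen_species if s not in header_species]
        if missing:
            raise CRNParseError(
                f"species {', '.join(missing)} appear in reactions but not in the species: header"
            )
        species = list(header_species)
    else:
        species = seen_species
    index = {s: i for i, s in enumerate(species)}

    def to_vec(d: dict[str, int]) -> ComplexVector:
        v = [0] * len(species)
        for k, c in d.items():
            v[index[k]] = c
        return ComplexVector(tuple(v))

    complexes: list[ComplexVector] = []
    cset: set[ComplexVector] = set()
    reactions: list[Reaction] = []
    labels_seen: set[str] = set()
    for lineno, reactant, product, label, _ in raw:
        if label in labels_seen:
            raise CRNParseError(f"duplicate rate label {label!r}", lineno)
        labels_seen.add(label)
        rc, pc = to_vec(reactant), to_vec(product)
        for cv in (rc, pc):
            if cv not in cset:
                cset.add(cv)
                complexes.append(cv)
        reactions.append(Reaction(rc, pc, label))

    return ReactionNetwork(species=species, complexes=complexes, reactions=reactions, name=name)


def to_crn(net: ReactionNetwork) -> str:
    """Serialize a network back to ``.crn`` text (irreversible lines only).

    ``parse_network(to_crn(net))`` reproduces the network exactly
    (species order is pinned by an explicit header).
    """
    lines = ["species: " + " ".join(net.species)]
    for rxn in net.reactions:
        lines.append(
            f"{rxn.reactant.format(net.species)} -> "
            f"{rxn.product.format(net.species)} ; {rxn.rate_label}"
        )
    return "\n".join(lines) + "\n"
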