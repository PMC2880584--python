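"""Shared fixtures and independent numeric oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.optimize
import sympy as sp

import crnsteady as cs

ISO_CRN = "A <-> B ; k1, k2\n"


@pytest.fixture(scope="session")
def edelstein():
    return cs.edelstein_network()


@pytest.fixture(scope="session")
def apoptosis():
    return cs.apoptosis_network()


@pytest.fixture(scope="session")
def iso_net():
    """Two-state isomerization A <-> B, the simplest conserved network."""
    return cs.parse_network(ISO_CRN, name="iso")


@pytest.fixture(scope="session")
def edelstein_basis(edelstein):
    """Lex basis for the Edelstein fixture with the total et symbolic."""
    et = sp.Symbol("et", positive=True)
    sysad = cs.build_ad_system(
        edelstein.network, edelstein.parameters, cs.CompatibilityClass([et]), "A"
    )
    return cs.groebner_elimination(sysad)


@pytest.fixture(scope="session")
def apoptosis_basis(apoptosis):
    et = sp.Symbol("et", positive=True)
    sysad = cs.build_ad_system(
        apoptosis.network, apoptosis.parameters, cs.CompatibilityClass([et]), "x4"
    )
    return cs.groebner_elimination(sysad)


# Independent oracles -----------------------------------------------------


def edelstein_cubic(k: dict, x1: sp.Symbol, et) -> sp.Expr:
    """Closed-form retained-variable cubic for the Edelstein network.

    Derived by hand from the reduced steady-state equations: substitute
    x3 = et - x2, solve the second equation linearly for x2, clear the
    denominator in the first.
    """
    k1, k2, k3, k4, k5, k6 = (sp.sympify(k[f"k{i}"]) for i in range(1, 7))
    return sp.expand(
        (k1 * x1 - k2 * x1**2 - k5 * et) * (k3 * x1 + k4 + k5 + k6)
        + (k5 + k6) * (k4 + k5) * et
    )


def multistart_positive_roots(
    net,
    rates,
    totals: list[float],
    n_starts: int = 300,
    seed: int = 0,
    tol: float = 1e-9,
):
    """Positive steady states of the *un-reduced* system {N.v = 0} u
    {conservation}, by seeded multi-start damped least squares.

    This is the independent cross-check for the Groebner route: it
    never touches RD, elimination, or back-substitution.
    """
    analysis = cs.analyze_network(net)
    x = list(sp.symbols(" ".join(net.species), positive=True))
    N = net.stoichiometric_matrix()
    v = sp.Matrix(cs.rate_vector(net, rates))
    eqs = list(N * v)
    for w, T in zip(analysis.conservation_vectors, totals):
        eqs.append(sum(int(wi) * xi for wi, xi in zip(w, x)) - T)
    F = sp.lambdify(x, eqs, "numpy")
    fun = lambda z: np.asarray(F(*z), dtype=float)
    scale = max([1.0, *map(float, totals)])
    rng = np.random.default_rng(seed)
    found: list[np.ndarray] = []
    for _ in range(n_starts):
        z0 = 10.0 ** rng.uniform(-4, np.log10(scale * 2), len(x))
        sol = scipy.optimize.root(fun, z0, method="lm", options={"maxiter": 2000})
        z = sol.x
        if not sol.success or np.any(z <= 1e-10 * scale):
            continue
        if np.max(np.abs(fun(z))) > tol * scale:
            continue
        if any(np.allclose(z, f, rtol=1e-6, atol=1e-8 * scale) for f in found):
            continue
        found.append(z)
    return sorted(found, key=lambda z: tuple(z))


def assert_point_sets_match(points, roots, scale=1.0, tol=1e-6):
    """Steady-state point list vs multistart root list, within tolerance."""
    assert len(points) == len(roots), (
        f"{len(points)} Groebner points vs {len(roots)} multistart roots"
    )
    got = sorted((np.asarray(p.concentrations) for p in points), key=tuple)
    for a, b in zip(got, sorted(roots, key=tuple)):
        np.testing.assert_allclose(a, b, rtol=tol, atol=tol * scale)
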