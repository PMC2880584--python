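"""Parameter scans: steady-state branches, counts, folds, multistationarity.

A bifurcation scan varies one parameter — a conserved total (moving the
compatibility class across the equilibrium variety) or a rate constant —
and records every positive steady state with its stability at each grid
point.  The scanned parameter is kept symbolic through a single
Groebner elimination, so the per-grid-point work is only univariate
root-finding plus back-substitution.

Fold (saddle-node) points, where the positive-steady-state count
changes, are refined by bisection on the count; maximal parameter
ranges with count >= 2 are reported as multistationarity intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import sympy as sp

from .conservation import CompatibilityClass, analyze_network
from .kinetics import MassActionSystem, RateConstants, species_symbols
from .network import ReactionNetwork
from .stability import classify_jacobian, subspace_basis
from .steady_state import build_ad_system, groebner_elimination, solve_triangular

__all__ = [
    "BifurcationDiagram",
    "scan_conserved_total",
    "scan_rate_constant",
    "multistationarity_interval",
]

DEFAULT_GRID = 200
FOLD_REL_WIDTH = 1e-6
FOLD_MAX_ITER = 60


@dataclass
class BifurcationDiagram:
    """Branches, counts and multistationarity structure over one scan."""

    parameter: str
    retained: str
    grid: np.ndarray
    counts: np.ndarray  # positive steady states per grid point
    branches: pd.DataFrame  # parameter, value (retained species), stability, branch
    fold_points: list[float]
    multistationarity_intervals: list[tuple[float, float]]
    points: list[list] = field(default_factory=list, repr=False)  # SteadyStatePoint per grid value
    _count_fn: Callable[[float], int] | None = field(default=None, repr=False)

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if len(self.counts) else 0


def _make_grid(lo: float, hi: float, n: int) -> np.ndarray:
    if not (0 < lo < hi):
        raise ValueError(f"scan range must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if hi / lo > 100.0:  # log spacing once the range spans > 2 decades
        return np.logspace(np.log10(lo), np.log10(hi), n)
    return np.linspace(lo, hi, n)


def _refine_fold(count_fn: Callable[[float], int], a: float, b: float) -> float:
    """Bisect [a, b] (counts differ at the ends) down to relative width 1e-6."""
    ca = count_fn(a)
    for _ in range(FOLD_MAX_ITER):
        if (b - a) <= FOLD_REL_WIDTH * max(abs(a), abs(b)):
            break
        m = 0.5 * (a + b)
        if count_fn(m) == ca:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _assemble_branches(grid, per_point, retained_idx) -> pd.DataFrame:
    """Greedy nearest-neighbor matching of retained values between grid points."""
    rows = []
    next_id = 0
    prev: list[tuple[float, int]] = []  # (retained value, branch id) at previous grid point
    for gval, pts in zip(grid, per_point):
        vals = [pt.concentrations[retained_idx] for pt, _ in pts]
        # globally greedy assignment by distance, so a surviving branch is
        # matched by the closest new point rather than the first one seen
        candidates = sorted(
            (abs(v - pval), i, j)
            for i, v in enumerate(vals)
            for j, (pval, _) in enumerate(prev)
        )
        assigned: dict[int, int] = {}
        used_prev: set[int] = set()
        for _, i, j in candidates:
            if i in assigned or j in used_prev:
                continue
            assigned[i] = prev[j][1]
            used_prev.add(j)
        cur: list[tuple[float, int]] = []
        for i, ((pt, label), val) in enumerate(zip(pts, vals)):
            bid = assigned.get(i)
            if bid is None:
                bid = next_id
                next_id += 1
            cur.append((val, bid))
            rows.append(
                {
                    "parameter": float(gval),
                    "value": float(val),
                    "stability": label,
                    "branch": bid,
                }
            )
        prev = cur
    return pd.DataFrame(rows, columns=["parameter", "value", "stability", "branch"])


def _intervals_from_counts(grid, counts, count_fn) -> tuple[list[float], list[tuple[float, float]]]:
    folds: list[float] = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            folds.append(_refine_fold(count_fn, float(grid[i]), float(grid[i + 1])))
    intervals: list[tuple[float, float]] = []
    in_multi = False
    lo = None
    fold_iter = iter(folds)
    # walk the grid; use refined folds as interval endpoints where available
    boundaries = folds
    bi = 0
    for i in range(len(grid)):
        multi = counts[i] >= 2
        if multi and not in_multi:
            if i > 0 and bi < len(boundaries):
                lo = boundaries[bi]
                bi += 1
            else:
                lo = float(grid[i])
            in_multi = True
        elif not multi and in_multi:
            if bi < len(boundaries):
                hi = boundaries[bi]
                bi += 1
            else:
                hi = float(grid[i])
            intervals.append((lo, hi))
            in_multi = False
        elif multi and i > 0 and counts[i] != counts[i - 1]:
            bi += 1  # fold inside a multistationary run (e.g. 3 -> 2 -> 3)
    if in_multi:
        intervals.append((lo, float(grid[-1])))
    return folds, intervals


def _run_scan(
    net: ReactionNetwork,
    basis,
    param: sp.Symbol,
    grid: np.ndarray,
    retained: str,
    jac_fn,
    B: np.ndarray,
    fixed_subs: dict,
) -> BifurcationDiagram:
    retained_idx = net.species.index(retained)

    def solve_at(value: float):
        return solve_triangular(basis, {**fixed_subs, param.name: value})

    def count_at(value: float) -> int:
        return len(solve_at(value))

    per_point = []
    counts = np.zeros(len(grid), dtype=int)
    points_per = []
    for i, gval in enumerate(grid):
        pts = solve_at(float(gval))
        labelled = []
        for pt in pts:
            J = jac_fn(float(gval), np.asarray(pt.concentrations))
            _, _, label = classify_jacobian(J, B)
            labelled.append((pt, label))
        counts[i] = len(pts)
        per_point.append(labelled)
        points_per.append(pts)

    folds, intervals = _intervals_from_counts(grid, counts, count_at)
    branches = _assemble_branches(grid, per_point, retained_idx)
    return BifurcationDiagram(
        parameter=param.name,
        retained=retained,
        grid=np.asarray(grid, dtype=float),
        counts=counts,
        branches=branches,
        fold_points=folds,
        multistationarity_intervals=intervals,
        points=points_per,
        _count_fn=count_at,
    )


def _param_jacobian(net: ReactionNetwork, rates, param: sp.Symbol):
    """Jacobian evaluator (param value, x) -> ndarray, lambdified once."""
    system = MassActionSystem(net, rates)
    J = system.jacobian()
    xs = species_symbols(net)
    fn = sp.lambdify((param, *xs), J.tolist(), "numpy")
    return lambda pval, x: np.asarray(fn(pval, *x), dtype=float)


def scan_conserved_total(
    net: ReactionNetwork,
    rates: RateConstants | dict,
    retained: str,
    lo: float,
    hi: float,
    grid: int = DEFAULT_GRID,
    scan_index: int = 0,
    other_totals: dict[int, float] | None = None,
    param_name: str = "et",
) -> BifurcationDiagram:
    """Scan one conserved total across [lo, hi].

    The scanned total stays symbolic through a single elimination; for
    networks with several conservation laws, ``other_totals`` fixes the
    rest (by conservation-vector index).
    """
    analysis = analyze_network(net)
    if analysis.n_conserved == 0:
        raise ValueError(
            "network has no conservation law; scan a rate constant instead "
            "(scan_rate_constant)"
        )
    param = sp.Symbol(param_name, positive=True)
    totals: list = []
    other_totals = dict(other_totals or {})
    for i in range(analysis.n_conserved):
        if i == scan_index:
            totals.append(param)
        elif i in other_totals:
            totals.append(other_totals[i])
        else:
            raise ValueError(f"no total supplied for conservation vector {i}")
    sys = build_ad_system(net, rates, CompatibilityClass(totals), retained, analysis)
    basis = groebner_elimination(sys)
    g = _make_grid(float(lo), float(hi), int(grid))
    jac_fn = _param_jacobian(net, rates, param)
    B = subspace_basis(analysis)
    return _run_scan(net, basis, param, g, retained, jac_fn, B, {})


def scan_rate_constant(
    net: ReactionNetwork,
    rates: RateConstants | dict,
    label: str,
    lo: float,
    hi: float,
    cls: CompatibilityClass | list,
    retained: str,
    grid: int = DEFAULT_GRID,
) -> BifurcationDiagram:
    """Scan one rate constant at fixed compatibility-class totals.

    The scanned constant is symbolic in the elimination, every other
    rate numeric.
    """
    if label not in net.rate_labels:
        raise ValueError(f"unknown rate label {label!r}")
    param = sp.Symbol(label, positive=True)
    base = rates.values if isinstance(rates, RateConstants) else dict(rates)
    scan_rates = {l: (param if l == label else v) for l, v in base.items()}
    analysis = analyze_network(net)
    sys = build_ad_system(net, scan_rates, cls, retained, analysis)
    basis = groebner_elimination(sys)
    g = _make_grid(float(lo), float(hi), int(grid))
    jac_fn = _param_jacobian(net, scan_rates, param)
    B = subspace_basis(analysis)
    return _run_scan(net, basis, param, g, retained, jac_fn, B, {})


def multistationarity_interval(diagram: BifurcationDiagram) -> list[tuple[float, float]]:
    """Refined (lo, hi) parameter ranges holding >= 2 positive steady states."""
    return list(diagram.multistationarity_intervals)
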