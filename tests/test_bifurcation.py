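"""Parameter scans: branch structure, fold points, multistationarity windows."""

import numpy as np
import pytest
import sympy as sp

import crnsteady as cs
from crnsteady.bifurcation import (
    multistationarity_interval,
    scan_conserved_total,
    scan_rate_constant,
)


@pytest.fixture(scope="module")
def edelstein_scan(edelstein):
    meta = edelstein.known_properties["scan"]
    return scan_conserved_total(
        edelstein.network, edelstein.parameters, "A", meta["lo"], meta["hi"], grid=120
    )


class TestEdelsteinTotalScan:
    def test_count_profile_one_three_one(self, edelstein_scan):
        counts = edelstein_scan.counts
        assert edelstein_scan.max_count == 3
        # collapse consecutive repeats -> the qualitative profile
        profile = [counts[0]]
        for c in counts[1:]:
            if c != profile[-1]:
                profile.append(c)
        assert list(profile) == [1, 3, 1]

    def test_exactly_two_folds_one_interval(self, edelstein_scan, edelstein):
        assert len(edelstein_scan.fold_points) == 2
        ivs = multistationarity_interval(edelstein_scan)
        assert len(ivs) == 1
        lo, hi = ivs[0]
        alo, ahi = edelstein.known_properties["window"]["approx_interval"]
        assert lo == pytest.approx(alo, rel=0.05)
        assert hi == pytest.approx(ahi, rel=0.05)

    def test_stability_alternates_along_retained_axis(self, edelstein_scan):
        """At every count-3 total: stable / unstable / stable in A order."""
        checked = 0
        for gval, n in zip(edelstein_scan.grid, edelstein_scan.counts):
            if n != 3:
                continue
            sel = edelstein_scan.branches[edelstein_scan.branches.parameter == gval]
            labels = sel.sort_values("value").stability.tolist()
            assert labels == ["stable", "unstable", "stable"]
            checked += 1
        assert checked > 0

    def test_branches_continuous_within_branch(self, edelstein_scan):
        br = edelstein_scan.branches
        for bid, sub in br.groupby("branch"):
            vals = sub.sort_values("parameter").value.to_numpy()
            if len(vals) < 3:
                continue
            jumps = np.abs(np.diff(vals))
            scale = max(1.0, np.max(np.abs(vals)))
            assert np.max(jumps) < 0.35 * scale  # bounded by grid resolution

    def test_interval_matches_discriminant_sign_change(self, edelstein, edelstein_basis, edelstein_scan):
        """Fold totals are roots of the discriminant of the retained cubic."""
        A = sp.Symbol("A", positive=True)
        et = sp.Symbol("et", positive=True)
        disc = sp.Poly(sp.discriminant(edelstein_basis.first_element, A), et)
        roots = np.roots([float(c) for c in disc.all_coeffs()])
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 * (1 + abs(r)))
        for fold in edelstein_scan.fold_points:
            assert min(abs(fold - r) for r in real) < 1e-4 * fold

    def test_grid_doubling_leaves_diagram_invariant(self, edelstein):
        meta = edelstein.known_properties["scan"]
        d1 = scan_conserved_total(
            edelstein.network, edelstein.parameters, "A", meta["lo"], meta["hi"], grid=60
        )
        d2 = scan_conserved_total(
            edelstein.network, edelstein.parameters, "A", meta["lo"], meta["hi"], grid=120
        )
        assert d1.max_count == d2.max_count == 3
        np.testing.assert_allclose(d1.fold_points, d2.fold_points, rtol=1e-5)


class TestDegenerateScans:
    def test_isomerization_always_monostationary(self, iso_net):
        d = scan_conserved_total(iso_net, {"k1": 2, "k2": 1}, "B", 0.5, 50.0, grid=40)
        assert set(d.counts.tolist()) == {1}
        assert d.fold_points == [] and d.multistationarity_intervals == []

    def test_no_conservation_law_directs_to_rate_scan(self):
        net = cs.parse_network("0 -> X ; ks\nX -> 0 ; kd")
        with pytest.raises(ValueError, match="rate constant"):
            scan_conserved_total(net, {"ks": 2, "kd": 1}, "X", 1, 10)

    def test_flat_branch_when_rate_has_no_influence(self, iso_net):
        """Scanning an outflow-balanced label in a linear network: the
        retained value moves smoothly and the count never changes."""
        d = scan_rate_constant(iso_net, {"k1": 2, "k2": 1}, "k2", 0.5, 5.0, ["6"], "B", grid=25)
        assert set(d.counts.tolist()) == {1}

    def test_unknown_rate_label(self, iso_net):
        with pytest.raises(ValueError, match="unknown rate label"):
            scan_rate_constant(iso_net, {"k1": 2, "k2": 1}, "nope", 0.1, 1, ["6"], "B")


class TestApoptosisScans:
    def test_total_c8_window_exists(self, apoptosis):
        meta = apoptosis.known_properties["window"]
        lo, hi = meta["approx_interval"]
        d = scan_conserved_total(
            apoptosis.network, apoptosis.parameters, "x4", 0.5 * lo, 2.0 * hi, grid=50
        )
        assert d.max_count == 3
        assert len(d.multistationarity_intervals) == 1
        assert len(d.fold_points) == 2

    def test_kd_scan_commutes_between_low_and_high_x4(self, apoptosis):
        """Varying BAR degradation at fixed total C8* switches the
        executioner-caspase level between regimes."""
        meta = apoptosis.known_properties["kd_scan"]
        d = scan_rate_constant(
            apoptosis.network,
            apoptosis.parameters,
            "kd",
            meta["lo"],
            meta["hi"],
            [meta["et"]],
            "x4",
            grid=30,
        )
        assert d.max_count >= 2  # a multistationary kd range exists
        lo_vals = d.branches[d.branches.parameter == d.grid[0]].value
        hi_vals = d.branches[d.branches.parameter == d.grid[-1]].value
        # the low-x4 (apoptosis-off) state exists at small kd and is gone
        # at large kd, where only the high-x4 state survives
        assert lo_vals.min() < 0.1
        assert hi_vals.min() > 1.0

    def test_edelstein_rate_scan_fold_structure_persists(self, edelstein):
        """Perturbing k6 around the fixture value keeps the bistable window."""
        k6 = float(edelstein.parameters["k6"])
        d = scan_rate_constant(
            edelstein.network, edelstein.parameters, "k6", 0.8 * k6, 1.25 * k6,
            ["20"], "A", grid=20,
        )
        assert d.max_count == 3
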