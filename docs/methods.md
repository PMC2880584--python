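# Methods

## Model and scope

`crnsteady` analyses chemical reaction networks with deterministic
mass-action kinetics in a well-stirred, isothermal reactor.  A network
is three ordered sets — species, complexes, reactions — from which the
complex matrix Y, incidence matrix Ia and stoichiometric matrix
N = Y·Ia are built in exact integer arithmetic.  Concentrations are in
mol/L (any consistent unit works); a rate constant for a reaction of
reactant molecularity m carries units time⁻¹·(mol/L)^(1−m).  Only
integer stoichiometry and mass-action rates are supported: no
Michaelis–Menten or Hill kinetics, no compartments, and no SBML import
— the `.crn` text dialect is the single input format.

The central object is the steady-state system inside one
stoichiometric compatibility class,

    AD = { RD·v(k,x) } ∪ { w·x − T per conservation law },

with RD the reduced row echelon form of N.  Using RD instead of N
drops the rank-redundant rows while preserving the solution set, so AD
is square (s equations, s unknowns) and, for generic parameters,
zero-dimensional.

## Exact arithmetic and the elimination step

All symbolic work uses exact rationals.  Rate constants given as
floats are converted through their shortest decimal representation
(0.1 → 1/10); conservation vectors are integer-normalized (gcd 1,
positive leading entry).  This is not cosmetic: Gröbner-basis
computation over floating-point coefficients is numerically fragile,
and the conservation equations must be *exactly* consistent with
RD·v for the elimination ideal to behave.

The elimination order puts the eliminated species first
(alphabetically, for reproducibility) and the retained reporter
species last.  Which species to retain is the user's choice — the
reporter whose branch diagram is wanted ([A] for the Edelstein
fixture, cleaved caspase-3 for the apoptosis fixture).  Rate constants
are substituted numerically before elimination, but the scanned
parameter (a conserved total, or one rate constant) stays symbolic in
the coefficient field, so a single Gröbner basis serves an entire
bifurcation scan; this is the main performance lever, reducing
per-grid-point work to univariate root-finding plus back-substitution.

Sympy's Gröbner engine is the production path.  A deliberately naive
Buchberger implementation (S-polynomials, full division,
inter-reduction; refuses > 3 variables or total degree > 4) lives in
`crnsteady.groebner` purely as an independent oracle for tests.

## Numeric root handling

Real roots of the retained-variable polynomial come from numpy's
companion-matrix solver with one Newton polish step, after exact
stripping of zero leading coefficients.  Tolerances:

* a complex root counts as real when |Im| ≤ 1e−9·max(1, |root|);
* a coordinate counts as positive when it exceeds 1e−10 × the largest
  class total (floating root-finders return tiny spurious parts);
* every candidate gets a short Newton polish on the full AD system,
  then must pass an *independent* residual check — ‖N·v(x)‖∞ below
  1e−9 × max(1, largest reaction rate) — computed by direct float
  evaluation of the reaction list, bypassing sympy and the solver path
  entirely.

Back-substitution branches on every real root of each univariate step
and discards branches with non-real or negative coordinates.  The
elimination polynomial can carry positive roots that do not extend to
a fully positive solution (observed in the apoptosis fixture, where a
degree-4 first element has at most 3 admissible roots); counting is
therefore always done after back-substitution, never on the first
element alone.  Boundary equilibria (some coordinate zero, e.g. the
origin of a closed network) are excluded from steady-state counts,
which concern interior states of a compatibility class; they can be
requested explicitly.

## Stability

The full Jacobian at an interior steady state always has s − rank(N)
zero eigenvalues, one per conservation law (wᵀJ = 0 identically).
These say nothing about stability inside the class, so classification
restricts J to the stoichiometric subspace T: with B an orthonormal
basis of T (SVD of N, keeping the exactly-known rank), the label comes
from eig(BᵀJB) — stable if all real parts < 0, unstable if any > 0,
marginal when a real part lies within 1e−8 × spectral radius of zero
(reported, never silently resolved).  The basis choice cannot affect
the spectrum (orthogonal similarity), which tests assert.  ODE
integration (LSODA with the analytic Jacobian, rtol 1e−9) provides the
dynamical cross-check: in-class perturbations of stable states decay
back; starts on either side of a saddle settle on the two different
attractors (hysteresis).

## Bifurcation scans

Default grid 200 points, log-spaced once the range spans more than two
decades.  Counts change only at folds; each grid interval where the
count changes is refined by bisection on the count to relative width
1e−6 (≤ 60 iterations).  Maximal ranges with count ≥ 2 are reported as
multistationarity intervals with the refined folds as endpoints.
Branches are assembled by globally-greedy nearest-neighbour matching of
reporter values between adjacent grid points; the matching is cosmetic
(for plotting and branch tables) and never feeds back into counts or
intervals.  For the Edelstein network the window can be checked
analytically: the fold totals are real roots of the discriminant of
the retained cubic, and tests verify the refined folds against them.

## Fixtures and the synthetic generator

**Edelstein network.**  Reactions A ↔ 2A, A + B ↔ C, C ↔ B; s = 3,
c = 5, r = 6, rank 2, conserved moiety B + C.  Eliminating by hand
(x₃ = et − x₂, the second reduced equation is linear in x₂) gives the
closed-form retained cubic

    (k₁x₁ − k₂x₁² − k₅·et)(k₃x₁ + k₄ + k₅ + k₆) + (k₅+k₆)(k₄+k₅)·et,

which the elimination must reproduce up to a nonzero scalar — the
sharpest oracle in the suite.

**Apoptosis network.**  The published reaction diagram for this model
is not machine readable, so the bundled list is a reconstruction built
to satisfy every stated constraint: seven species, fourteen reactions,
conservation of total activated caspase-8 (x1 + x3 + x6 + x7), BAR
degradation governed by kd, caspase-8-mediated caspase-3 activation
and BAR binding to both free and substrate-bound caspase-8.  The
fourteen reactions are the binding/unbinding/cleavage core
(x1+x2 ↔ x3 → x1+x4), BAR binding (x1+x5 ↔ x6, x3+x5 ↔ x7), turnover
(0 ↔ x2, 0 → x5, x5 → 0 with rate kd, x4 → 0) and in-complex BAR
turnover releasing the caspase moiety (x6 → x1, x7 → x3).  The
in-complex BAR turnover rates differing from the free-BAR rate is what
makes the conserved-total load curve non-monotone and hence
bistability possible; with equal in-complex rates the steady state is
provably unique for this topology.

**Rate sets.**  Both fixtures' rate constants are the output of
`bistable_parameter_search` — log-uniform draws on [10⁻², 10²] rounded
to two significant digits (kept as exact rationals so the elimination
stays fast), accepted when the retained-variable polynomial has ≥ 3
positive roots at some total (exact Sturm count) *and* full
back-substitution confirms ≥ 3 interior states.  The searches are
seeded (seed 1 for both; hits at draws 1 and 3) and the regeneration
script re-runs them; the parameter files record seed, draw index and
the measured windows.  They are study conditions, not fitted values:
no published parameterization was available to compare against.

**Random networks.**  The generator draws complexes of total
stoichiometry ≤ 2 and rejects candidate reactions whose reaction
vector is not annihilated by every planted conservation vector, so
planted left-null vectors are conservation laws by construction; with
no planted laws and r ≥ s it redraws until N has full rank.  Outputs
are deterministic in the seed and round-trip through the `.crn`
serializer.  What the generator does *not* emulate: realistic kinetic
time-scale separation, thermodynamic consistency (Wegscheider
conditions), or biologically structured topology — passing tests on
these networks validates the algebra and the conservation handling,
not biological realism.

## Problem sizes and costs

The symbolic elimination is the expensive step and scales badly in
general (lex Gröbner bases are doubly exponential in the worst case);
this package targets the small, biologically interpretable networks
the method suits — the 7-species apoptosis elimination with a symbolic
total runs in well under a second, and a 200-point total scan with
stability labels in a few seconds.  Test and acceptance runs use grids
of 50–200 points, 250–350 multi-start root searches, and 50 random
networks; these sizes give stable results while keeping the whole
suite quick.  Larger networks may require substituting all parameters
numerically before elimination, or fail to finish; subnetwork
decomposition is out of scope.

## Known limitations

* Positive-dimensional steady-state varieties (degenerate parameter
  choices) are detected only indirectly (no retained-block univariate
  polynomial) and raise, rather than being parameterized.
* Marginal labels at fold points are reported as such; the package
  does not attempt center-manifold analysis.
* Fold refinement bisects on the integer count, so a window narrower
  than the scan grid spacing can be missed entirely.
* The apoptosis fixture is a reconstruction; conclusions about the
  published model's quantitative windows do not transfer.
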