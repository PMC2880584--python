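# crnsteady

Analytical steady-state detection and multistationarity mapping for
mass-action chemical reaction networks (CRNs).

Many regulatory networks in cell biology — apoptosis commitment being
the canonical example — are bistable: within a single conserved pool of
material the dynamics admits two stable steady states separated by an
unstable one, and the cell's fate depends on which basin it sits in.
Deciding *where* in parameter space this happens requires solving the
polynomial steady-state equations exactly, not just simulating
trajectories.  `crnsteady` does this with computer algebra: it is aimed
at systems biologists and modellers who have a reaction list and want
the full set of positive steady states, their stability, and the
parameter windows of multistationarity.

## The method

A CRN with species set 𝒮 (|𝒮| = s), complex set 𝒞 and reaction set ℛ
(|ℛ| = r) defines the complex matrix Y (s×c), the incidence matrix Ia
(c×r, one −1/+1 pair per column) and the stoichiometric matrix
N = Y·Ia.  Mass-action kinetics assigns reaction j the rate
v_j = k_j ∏ᵢ xᵢ^{yᵢⱼ} over its reactant complex, giving the polynomial
ODE system

    dx/dt = N v(k, x).

Left-null vectors w of N (wᵀN = 0) are conserved moieties: w·x is
constant, so trajectories live in stoichiometric compatibility classes
{x : w·x = T}.  Steady states in one class solve the square system

    AD = { RD · v(k, x) }  ∪  { w·x − T }

where RD is the reduced row echelon form of N (computed in exact
rational arithmetic).  A Gröbner basis of AD in lexicographic order
with a chosen reporter species last is echelon-shaped: its first
element is a univariate polynomial in the reporter whose coefficients
may still contain a symbolic total T, and back-substitution recovers
the remaining coordinates.  Real positive roots are counted and
polished, stability is read off the Jacobian restricted to the
stoichiometric subspace (the full Jacobian always has s − rank(N)
structural zero eigenvalues), and scanning T — or a rate constant —
yields the bifurcation diagram, fold points and the multistationarity
interval.

## Worked example

The bundled Edelstein network (`A <-> 2A`, `A + B <-> C`, `C <-> B`;
autocatalytic production of A with enzyme-like removal, B + C
conserved) ships with a rate set found by the package's seeded search.
Scanning the conserved total:

```
$ crnsteady bifurcate --network edelstein.crn --params edelstein_params.yaml \
      --retain A --scan total:et --range 1:100 --grid 120 --branches-out /dev/null
{
  "parameter": "et",
  "retained": "A",
  "grid": [1.0, 100.0],
  "grid_size": 120,
  "max_count": 3,
  "fold_points": [14.60122366512523, 30.93771067386916],
  "multistationarity_intervals": [[14.60122366512523, 30.93771067386916]]
}
```

The system is bistable for conserved totals et between ≈14.6 and
≈30.9: three positive steady states (outer two stable, middle one a
saddle), merging pairwise at the two fold points.  Inside the window:

```
$ crnsteady steady-states --network edelstein.crn --params edelstein_params.yaml \
      --retain A --total et=20
```

returns three states with `[A]` ≈ 0.0040 (stable), 3.74 (unstable) and
35.6 (stable), each with residual ‖N·v‖∞ below 10⁻¹³ and the real
parts of the reduced Jacobian eigenvalues that justify the label.

The second bundled fixture is a seven-species, fourteen-reaction
receptor-induced apoptosis model (caspase-8 activates caspase-3; the
inhibitor BAR sequesters caspase-8), whose conserved total of activated
caspase-8 likewise has a three-state window, and whose BAR-degradation
rate `kd` switches the cleaved-caspase-3 level between low and high
regimes.  See `docs/methods.md` for the model and its provenance.

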