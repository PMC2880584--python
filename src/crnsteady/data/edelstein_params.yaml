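# Rate constants for the Edelstein fixture, produced by
# crnsteady.fixtures.bistable_parameter_search (see `search:` below).
# Values are exact rationals; the conserved total B + C ("et") has a
# three-steady-state window, re-measured by tests, near `window:`.
rates:
  k1: "20"        # A -> 2A, autocatalysis
  k2: "43/100"    # 2A -> A
  k3: "8/5"       # A + B -> C
  k4: "13/1000"   # C -> A + B
  k5: "10"        # C -> B
  k6: "7/5"       # B -> C
retained: A
search:
  seed: 1
  n_draws: 400
  draw_index: 1
  sampling: log-uniform on [1e-2, 1e2], rounded to 2 significant digits
window:
  parameter: et
  witness: "40093/2500"   # total with 3 positive steady states (search output)
  approx_interval: [14.6, 30.9]   # measured by scan_conserved_total, grid 200
scan:
  lo: 1.0
  hi: 100.0
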