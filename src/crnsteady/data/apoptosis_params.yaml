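# Rate constants for the reconstructed apoptosis fixture, produced by
# crnsteady.fixtures.bistable_parameter_search (see `search:` below).
# These are search output, not literature values: the network is a
# documented reconstruction and its published parameterization is not
# machine readable.  Total C8* (x1 + x3 + x6 + x7, "et") has a
# three-steady-state window, re-measured by tests, near `window:`.
rates:
  k1: "12/5"      # x1 + x2 -> x3   C8* binds C3
  k2: "11/100"    # x3 -> x1 + x2   unbinding
  k3: "23"        # x3 -> x1 + x4   cleavage: C3* release
  k4: "11/10"     # x1 + x5 -> x6   BAR binds C8*
  k5: "11/10"     # x6 -> x1 + x5   unbinding
  k6: "10"        # x3 + x5 -> x7   BAR binds C8*C3
  k7: "39/1000"   # x7 -> x3 + x5   unbinding
  k8: "19"        # 0 -> x2         C3 synthesis
  k9: "27/5"      # x2 -> 0         C3 turnover
  k10: "14"       # 0 -> x5         BAR synthesis
  kd: "29/500"    # x5 -> 0         free-BAR degradation (scan parameter)
  k12: "16"       # x4 -> 0         C3* clearance
  k13: "29/500"   # x6 -> x1        in-complex BAR turnover
  k14: "21/1000"  # x7 -> x3        in-complex BAR turnover
retained: x4
search:
  seed: 1
  n_draws: 60
  draw_index: 3
  sampling: log-uniform on [1e-2, 1e2], rounded to 2 significant digits
window:
  parameter: et
  witness: "550"                   # inside the window; search witness 277051/500
  approx_interval: [483.0, 614.0]  # measured by scan_conserved_total, grid 120
scan:
  lo: 50.0
  hi: 5000.0
kd_scan:
  et: "550"
  lo: 0.005
  hi: 0.5
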