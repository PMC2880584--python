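# Receptor-induced apoptosis network (reconstruction; see fixtures module).
# x1 = C8*   activated caspase-8 (initiator)
# x2 = C3    procaspase-3
# x3 = C8*C3 enzyme-substrate complex
# x4 = C3*   activated (cleaved) caspase-3, the executioner readout
# x5 = BAR   bifunctional apoptosis regulator (inhibitor)
# x6 = C8*BAR
# x7 = C8*C3BAR
# Total C8* = x1 + x3 + x6 + x7 is conserved; kd is free-BAR degradation.
species: x1 x2 x3 x4 x5 x6 x7
x1 + x2 <-> x3 ; k1, k2
x3 -> x1 + x4 ; k3
x1 + x5 <-> x6 ; k4, k5
x3 + x5 <-> x7 ; k6, k7
0 -> x2 ; k8
x2 -> 0 ; k9
0 -> x5 ; k10
x5 -> 0 ; kd
x4 -> 0 ; k12
x6 -> x1 ; k13
x7 -> x3 ; k14
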