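# Edelstein autocatalytic network: autocatalytic production of A
# followed by its enzyme-like removal through the B/C cycle.
# B + C is conserved (the total enzyme moiety).
species: A B C
A <-> 2A ; k1, k2
A + B <-> C ; k3, k4
C <-> B ; k5, k6
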