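# fig1_n1: 13 nodes on taxa {1,2,3,4}.
# Non-trivial first-order classes: {C,E}, {D,F}, {H,J}; second-order: {H,J};
# third-order partition discrete.  Third-order reduced.
edge R H
edge R J
edge R W1
edge R W2
edge H C
edge H D
edge J E
edge J F
edge W1 E
edge W1 4
edge W2 F
edge W2 3
edge C 1
edge C 2
edge E 1
edge E 2
edge D 3
edge D 4
edge F 3
edge F 4
leaf 1 1
leaf 2 2
leaf 3 3
leaf 4 4
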