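# fig1_n2: like fig1_n1 but the attachments of the order-1-equivalent pairs
# under H and J are exchanged (H -> C,F and J -> E,D).  The swap is invisible
# to orders 1 and 2 (H and J are second-order equivalent) but visible at
# order 3, and the two networks are not isomorphic.
edge R H
edge R J
edge R W1
edge R W2
edge H C
edge H F
edge J E
edge J D
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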