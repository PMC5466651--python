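# fig2_n1: 13 nodes on taxa {1..6}.  All within-network order-1 classes are
# singletons; against fig2_n2 the nodes R, B, F have no first-order
# equivalent partner, every other node exactly one (with class size 1).
edge R B
edge R F
edge B G
edge B M
edge F C
edge F M
edge G A
edge G C
edge A 1
edge A 2
edge C 3
edge C 4
edge M 5
edge M 6
leaf 1 1
leaf 2 2
leaf 3 3
leaf 4 4
leaf 5 5
leaf 6 6
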