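# fig3_n2: 15 nodes on taxa {1..6}.  Shares the unfoldings of A, C, G, K, M
# and the leaves 1..5 with fig3_n1; the nodes R, B, F, H and the leaf 6 have
# no first-order equivalent partner in fig3_n1.
edge R B
edge R F
edge B H
edge B K
edge F A
edge F H
edge H M
edge H 6
edge M G
edge M K
edge G A
edge G C
edge K C
edge K 5
edge A 1
edge A 2
edge C 3
edge C 4
leaf 1 1
leaf 2 2
leaf 3 3
leaf 4 4
leaf 5 5
leaf 6 6
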