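# fig3_n1: 13 nodes on taxa {1..5} (a strict subset of fig3_n2's taxa).
# Against fig3_n2 the nodes R, B, F have no first-order equivalent partner.
edge R B
edge R F
edge B M
edge B K
edge F A
edge F M
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
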