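# fig7_n: a network outside every order-k reduced space: A and B share both
# their parent (R) and their children (the leaves 1, 2), so A and B are
# kth-order equivalent for every k.
edge R A
edge R B
edge A 1
edge A 2
edge B 1
edge B 2
leaf 1 1
leaf 2 2
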