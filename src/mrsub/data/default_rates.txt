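# Default strand-symmetric substitution rates (trained on fourfold
# degenerate sites of human-referenced vertebrate alignments).
kind=symmetric
alpha=0.16
beta=0.57
gamma=0.20
delta=0.24
epsilon=0.59
eta=0.25
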