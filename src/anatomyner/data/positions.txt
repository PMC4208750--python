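# Positional modifiers that combine with anatomy terms (Dictionary-2).
# Editable: one term per line, '#' starts a comment.
left
right
bilateral
bilat
distal
proximal
upper
lower
anterior
posterior
medial
lateral
superior
inferior
dorsal
ventral
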