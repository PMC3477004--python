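# Raf signalling pathway gold standard: 11 phosphoproteins/phospholipids,
# 20 directed edges. Transcribed from the currently accepted consensus
# network of the single-cell flow-cytometry study of the Raf pathway
# (Sachs et al.), the standard benchmark for this system.
# nodes: Raf,Mek,Erk,PLCg,PIP2,PIP3,PKC,PKA,Akt,P38,Jnk
parent	child
PIP3	PLCg
PIP3	PIP2
PIP3	Akt
PLCg	PIP2
PLCg	PKC
PIP2	PKC
PKC	PKA
PKC	Raf
PKC	Mek
PKC	Jnk
PKC	P38
PKA	Raf
PKA	Mek
PKA	Erk
PKA	Akt
PKA	Jnk
PKA	P38
Raf	Mek
Mek	Erk
Erk	Akt
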