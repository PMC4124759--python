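protein_id	term_id
P1	IPR2
P1	IPR3
P1	IPR4
P2	IPR1
P2	IPR2
P2	IPR5
P3	IPR6
P4	IPR1
P4	IPR2
P4	IPR3
P4	IPR6
P5	IPR2
P5	IPR4
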