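#anchor=0
pos	1	2	3	4	5	6
A	0.02	0.02	0.60	0.70	0.08	0.15
C	0.02	0.02	0.12	0.08	0.06	0.15
G	0.94	0.02	0.12	0.10	0.80	0.20
T	0.02	0.94	0.16	0.12	0.06	0.50
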