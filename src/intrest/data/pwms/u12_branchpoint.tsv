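#anchor=7
pos	1	2	3	4	5	6	7	8	9
A	0.05	0.05	0.08	0.06	0.05	0.04	0.70	0.97	0.10
C	0.10	0.08	0.75	0.78	0.10	0.08	0.10	0.01	0.65
G	0.05	0.07	0.07	0.06	0.05	0.06	0.10	0.01	0.10
T	0.80	0.80	0.10	0.10	0.80	0.82	0.10	0.01	0.15
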