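#anchor=0
pos	1	2	3	4	5	6	7	8
A	0.40	0.01	0.97	0.02	0.03	0.04	0.05	0.06
C	0.03	0.02	0.01	0.02	0.90	0.88	0.05	0.07
G	0.55	0.02	0.01	0.01	0.04	0.04	0.05	0.07
T	0.02	0.95	0.01	0.95	0.03	0.04	0.85	0.80
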