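haplogroup	parent	defining_variants
R		
R0	R	C73T,C263T
HV	R0	T2706C,A7028G
H	HV	A750G,C1438T
H1	H	C3010T,T6776C
H1a	H1	A4793G,A9123G
V	HV	T4580C,A15904G
JT	R	G295A,T489C
J	JT	A10398G,A12612G
J1	J	C462T,G3394A
T	JT	G709A,C8697T
T2	T	C11812T,G14233A
U	R	A11467G,C12308T
U5	U	A3197G,T9477C
U5a	U5	A14793G,T15218C
K	U	G1189A,A10550G
M	R	A8701G,A9540G,T10873C
M1	M	T6446C,A12403G
D	M	C4883T,A5178G
D4	D	C8414T,T14668C
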