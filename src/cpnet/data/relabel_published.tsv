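# assigned -> published haplotype letters, for samples expanded
# from the packaged site table in row order
A	J
B	E
C	M
D	C
E	G
F	N
G	A
H	K
I	O
J	H
K	D
L	U
M	V
N	L
O	R
P	W
Q	S
R	I
S	F
T	B
U	T
V	P
W	Q
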