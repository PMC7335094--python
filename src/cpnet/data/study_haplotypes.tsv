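haplotype	trnL-trnF|260|260|substitution	atpB-rbcL|74|74|substitution	rps16|104|104|substitution	rps16|123|123|substitution	rps16|195|195|substitution	rps16|425|429|indel	rps16|532|532|indel	rps16|533|533|indel	rps16|699|699|substitution	rps16|703|703|substitution	trnG|9|9|substitution	trnG|256|256|indel	trnG|266|266|indel	trnG|278|278|indel	trnG|280|280|substitution	trnG|431|431|substitution	psbA-trnH|22|22|substitution	psbA-trnH|134|134|indel	psbA-trnH|141|145|indel	psbA-trnH|146|146|substitution	psbA-trnH|175|175|substitution	psbA-trnH|179|179|substitution	psbA-trnH|180|180|substitution	psbA-trnH|181|181|substitution	psbA-trnH|182|182|substitution	psbA-trnH|186|186|substitution	psbA-trnH|253|253|substitution	rpl32-trnL|6|6|substitution	rpl32-trnL|128|128|substitution	rpl32-trnL|169|169|substitution	rpl32-trnL|220|220|indel	rpl32-trnL|288|288|substitution	rpl32-trnL|353|353|indel	rpl32-trnL|354|354|indel	rpl32-trnL|366|366|indel	rpl32-trnL|380|380|substitution	rpl32-trnL|381|381|substitution	rpl32-trnL|382|382|substitution	rpl32-trnL|383|383|substitution	rpl32-trnL|384|384|substitution	rpl32-trnL|522|522|substitution	rpl32-trnL|530|530|substitution
A	A	A	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	-	-	A	C	T	G	G	T	A	T	A	G	T	T	C	-	-	T	T	A	T	C	C	T	C
B	A	A	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	-	-	A	C	T	G	G	T	A	T	A	G	T	T	C	A	-	T	T	A	T	C	C	T	C
C	A	A	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	T	T	C	-	-	T	T	A	T	C	C	T	C
D	A	A	G	G	T	-	-	T	T	C	T	-	T	-	T	C	T	-	-	A	C	T	G	G	T	A	T	G	G	A	-	C	A	-	-	T	A	T	C	C	T	C
E	A	C	G	G	T	-	-	T	T	C	T	-	T	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
F	A	C	G	G	T	-	-	-	T	C	T	-	T	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
G	A	C	G	G	T	-	-	T	T	C	T	-	T	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	G
H	A	C	G	G	T	-	-	T	T	C	T	-	T	-	T	A	T	A	-	C	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
I	A	C	G	G	T	-	-	T	T	C	T	-	T	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	T	A	T	C	-	-	T	T	A	T	C	C	T	C
J	A	C	G	G	T	-	-	T	T	C	T	-	-	-	T	A	G	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	-	-	-	T	A	T	C	C	T	C
K	A	C	G	G	C	-	-	T	A	T	T	-	-	-	T	A	G	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	-	-	-	T	A	T	C	C	T	C
L	A	C	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	-	AGTAA	A	C	T	G	G	T	A	T	A	G	T	T	C	-	-	T	T	A	T	C	C	T	C
M	A	C	G	G	T	-	-	T	T	C	T	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
N	A	C	G	G	T	ACTAT	-	-	T	C	T	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
O	A	C	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	A	-	-	T	A	T	C	C	T	C
P	A	C	G	G	T	-	-	T	T	C	A	-	-	-	T	A	T	-	-	A	C	T	G	G	T	A	T	A	G	T	T	C	-	-	T	T	A	T	C	C	T	C
Q	A	C	G	G	T	-	-	T	T	C	T	-	-	-	G	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	-	-	-	T	A	T	C	C	G	C
R	A	C	G	A	T	-	T	T	T	C	T	C	-	-	T	A	T	-	-	A	C	T	G	G	T	A	C	A	T	A	T	C	A	A	T	G	G	A	T	A	T	C
S	A	C	A	G	T	-	-	-	T	C	T	-	T	-	T	A	T	-	-	A	C	T	G	G	T	A	T	A	G	A	T	G	-	-	T	T	A	T	C	C	T	C
T	A	C	A	G	T	-	-	T	T	C	T	-	T	A	T	A	T	-	-	A	C	T	G	G	T	A	T	A	G	A	T	G	-	-	T	T	A	T	C	C	T	C
U	A	C	G	G	T	-	-	-	T	C	A	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	T	T	C	A	A	T	T	A	T	C	C	T	C
V	A	C	G	G	T	-	-	-	T	C	T	-	-	-	T	A	T	A	-	A	C	T	G	G	T	A	T	A	G	A	T	C	-	-	-	T	A	T	C	C	T	C
W	C	C	G	G	T	ACTAT	-	-	T	C	T	-	T	-	T	A	T	A	-	A	T	A	C	C	A	G	T	A	G	A	T	C	-	-	-	T	A	T	C	C	T	C
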