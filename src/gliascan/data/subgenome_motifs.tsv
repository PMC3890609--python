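motif	subgenome
YS	A
PQLPYL	B
PPQLPYP	B
LPQLPYP	B
QLPYPQPQPFPP	B
PQPQLPYPQ	D
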