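name	parent	status	core
DQ2.5-glia-a1a	a1	canonical	PFPQPQLPY
DQ2.5-glia-a1b	a1	canonical	PYPQPQLPY
a1a-variant-1	a1	variant	PFLQPQLPY
a1a-variant-2	a1	variant	PFPQPQLSY
a1a-variant-3	a1	variant	PFSQPQLPY
a1a-variant-4	a1	variant	PFPPPQLPY
a1a-variant-5	a1	variant	PFPQLQLPY
DQ2.5-glia-a2	a2	canonical	PQPQLPYPQ
a2-variant-1	a2	variant	PQPQLPYSQ
a2-variant-2	a2	variant	SQPQLPYSQ
a2-variant-3	a2	variant	PQPQLSYSQ
a2-variant-4	a2	variant	PPPQLPYSQ
a2-variant-5	a2	variant	LQPQLPYSQ
a2-variant-6	a2	variant	FPPQLPYPQ
a2-variant-7	a2	variant	FLPQLPYPQ
DQ2.5-glia-a3	a3	canonical	FRPQQPYPQ
a3-variant-1	a3	variant	FPPQQPYPQ
a3-variant-2	a3	variant	FSPQQPYPQ
a3-variant-3	a3	variant	FLPQQPYPQ
a3-variant-4	a3	variant	FPSQQPYPQ
a3-variant-5	a3	variant	FPPQQSYPQ
a3-variant-6	a3	variant	FQPQQPYPQ
a3-variant-7	a3	variant	FRPQQSYPQ
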