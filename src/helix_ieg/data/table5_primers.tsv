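gene	direction	sequence	product_length
c-fos	forward	TTACACCCCCATTCATCCGC	138
c-fos	reverse	AATACGTCCCCAGCGAACTG	138
beta-actin	forward	AGTGCTTGCCTTGTATGCCT	185
beta-actin	reverse	AACTTAAGCCCCTTCCTGCC	185
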