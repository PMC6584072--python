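contig_id	sequence	length	gc_content
1398029	TCGACCATGCTTTGCTTTTGGCTCCCATTCTGCATCAGAATATTCCG	47	46.81
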