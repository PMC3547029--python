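chrom	pos	rate
chr1	0	1.2
chr1	40000	1.2
chr1	80000	0.4
chr1	120000	0.1
chr1	160000	0.8
chr1	200000	1.5
chr1	240000	1.5
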