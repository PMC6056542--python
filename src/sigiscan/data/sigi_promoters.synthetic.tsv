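# SYNTHETIC stand-in promoter table (not transcribed from any publication figure).
# Six records per sigma class sampled from the package default per-sigma generators
# (seeds 42..46): concrete triad/tetrad/A-tract/dyad cores, IUPAC-degenerate gap and
# downstream positions realized uniformly. Schema: sigma_label, gene_label,
# specificity_seq, atract_seq, spacer_seq, minus10_seq, utr5.
sigma_label	gene_label	specificity_seq	atract_seq	spacer_seq	minus10_seq	utr5
sigI1	sigI1_s000	CTC	AAAAA	TTATTTACCTGTCA	CGAATGTATT	148
sigI1	sigI1_s001	CTC	AAAAA	TGTCTTTACAAGTTC	CGAATGTATT	47
sigI1	sigI1_s002	CTC	AAAA	AACAGCTTCTTC	CGAATGTATT	157
sigI1	sigI1_s003	CTC	AAAA	AAATGTTCGAAG	CGAATGTATT	214
sigI1	sigI1_s004	CTC	AAAA	TGGGAACACTAAAAG	CGAATGTATT	183
sigI1	sigI1_s005	CTC	AAAAA	GCTAAATCAGATCC	CGAATGTATT	242
sigI2	sigI2_s000	TGC	AAAAA	ATGATACCTTAAC	CGAATGTATT	41
sigI2	sigI2_s001	TGC	AAAA	TTGCTGTTAATAC	CGAATGTATT	113
sigI2	sigI2_s002	TGC	AAAA	ACGACGACCAGAGA	CGAATGTATT	179
sigI2	sigI2_s003	TGC	AAAAA	AACCGAATCGTT	CGAATGTATT	260
sigI2	sigI2_s004	TGC	AAAAAA	AACGGTTCAGTTG	CGAATGTATT	117
sigI2	sigI2_s005	TGC	AAAAA	GGCCCTGTGGTTA	CGAATGTATT	254
sigI3	sigI3_s000	CCCTC	AAAA	TATACGGTCTTTAT	CGAATGTATT	139
sigI3	sigI3_s001	CCCCT	AAAAA	ATAGAATAGTAATCA	CGAATGTATT	83
sigI3	sigI3_s002	CCCCC	AAAAAA	GATCTTATTGTATC	CGAATGTATT	205
sigI3	sigI3_s003	CCCTC	AAAAA	TTAACCTCTTATCCG	CGAATGTATT	133
sigI3	sigI3_s004	CCCTC	AAAA	GAAATGTGATGTA	CGAATGTATT	104
sigI3	sigI3_s005	CCCTC	AAAAAA	CTACTGTTATGAATT	CGAATGTATT	144
sigI4	sigI4_s000	GGT	AAAAA	TTGTTGCGGTTGTC	CGAATGTATT	173
sigI4	sigI4_s001	GGT	AAAAAA	GAAATATCCAAATAT	CGAATGTATT	264
sigI4	sigI4_s002	GGT	AAAAA	TCACAATCTAATT	CGAATGTATT	171
sigI4	sigI4_s003	GGT	AAAAA	CCCTCCTGGACTAT	CGAATGTATT	251
sigI4	sigI4_s004	GGT	AAAAA	TGCGAAAACGATC	CGAATGTATT	60
sigI4	sigI4_s005	GGT	AAAAA	TAATTGTACCAAGAC	CGAATGTATT	217
sigI6	sigI6_s000	GTT	AAAAAA	AGTAGTGTTCTA	CGAATGTATT	50
sigI6	sigI6_s001	GTT	AAAAA	AACCATAAGCGG	CGAATGTATT	239
sigI6	sigI6_s002	GTT	AAAA	GTGTCTAAAGCACAC	CGAATGTATT	228
sigI6	sigI6_s003	GTT	AAAAAA	CCAGAACAGGCACTG	CGAATGTATT	168
sigI6	sigI6_s004	GTT	AAAAAA	TCCCATACTGTACG	CGAATGTATT	70
sigI6	sigI6_s005	GTT	AAAA	AGCTCGGTCGAATT	CGAATGTATT	171
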