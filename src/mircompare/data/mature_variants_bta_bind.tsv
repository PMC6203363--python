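precursor_name	mature_name	chrom	seq_taurine	seq_indicine	reported_type	reported_region
bta-mir-2284e	bta-miR-2284e	chrX	AAGTTCGTTCGGATTTTTCC	AAGTTCATTCGGATTTTTCC	1S	Seed
bta-mir-2284l	bta-miR-2284l	chr3	AAAAGTTGGTTCGGGTTTTT	AAAAGTTCGTTCAGGTTTTT	2S	Mature
bta-mir-2284y-4	bta-miR-2284y-4	chr24	AAAAGTTCGTTCGGGTTTTTC	AAAAGTTCATTTGGGTTTTTC	2S	Mature
bta-mir-2284y-7	bta-miR-2284y-7	chr3	CGGGGGTGGCGGGGAGGGGG	CGGGGGTGGCGGGGAGCGGG	1S	Mature
bta-mir-2305	bta-miR-2305	chr13	AAAAAAGTTTGTTTGGGTTTTTT	AAAAAAGTTTGTGTGGGTTTTTT	1S	Mature
bta-mir-2403	bta-miR-2403	chr28	CTCGGGAAGCTAGCTGGCCTT	CTCAGGAAGCTAGCTGGCCTT	1S	Mature,seed
bta-mir-2421	bta-miR-2421	chr4	AAAAACCCGAATGAACTTTTTGG	AAAAAACTGAATGAACTTTTTGG	2S	Mature,seed
bta-mir-2467	bta-miR-2467	chr8	ACCCCAAGCCTGGCTGCTA	ACCCCAAGCCTGGCCGCTA	1S	Mature,Seed
bta-mir-2284w	bta-miR-2284w	chr9	AAAAGTTCGTTCGGGTTTTTC	AAAAGTTCATTCGGGTTTTTC	1S	Mature
bta-mir-2284z-1	bta-miR-2284z-1	chr10	CTCGGGAAGCTAGCTGGCCTT	CTCAGGAAGCTAGCTGGCCTT	1S	Seed
bta-mir-2284z-2	bta-miR-2284z-2	chr11	TATTTTTTTGTTTCGTGTTT	TATTTTTTTGTTTCATGTTT	1S	Mature
bta-mir-2284z-5	bta-miR-2284z-5	chr5	ACCCCAAGCCTGGCTGCT	ACCCCAAGCCTGGCCGCT	1S	Mature
bta-mir-2285l	bta-miR-2285l	chr12	AAGAGTTTGTTCGGGTTT	AAGAGTATGTTGGGGTTT	2S	Mature,seed
bta-mir-2285n-6	bta-miR-2285n-6	chr1	AAAAAAGTTTGTTTGGGTTTTT	AAAAAAGTTTATTTGGGTTTTT	1S	Mature,seed
bta-mir-2285o-5	bta-miR-2285o-5	chr5	AAAAAAGTTTGTTTGGGTTTTT	CAAAAAGTTTGTTTGGGTTTTT	1S	Mature
bta-mir-6522	bta-miR-6522	chr21	TCGGAATTGTTTGTGTACCTGT	TTGGAATTGTTTGTGTACTTGT	2S	Mature,seed
bta-mir-664a	bta-miR-664a	chr28	CAGGCTAGGAGGTGTGTGTGGATG	CAGGCTAGGAGGTAAGAGTGGATG	3S	Mature
bta-mir-2285l	bta-miR-2285l	chr12	AAAACCCGCATGAACTTTTTGGC	AAAACCCGAATGAACTTTTTAGC	2S	Mature
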