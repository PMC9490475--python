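# BLK-CS-11 credible set: 11 promoter SNPs in near-perfect LD.
# The risk/non-risk allele columns spell the published haplotype strings
# CCCCTTAAACA (risk) and TGTACCGGGTG (non-risk), in order.  The rs numbers
# of the member SNPs are supplementary-only, so the snp_id and pos columns
# here are synthetic placeholders inside the promoter window.
order	snp_id	pos	nonrisk_allele	risk_allele
1	cs11_01	11349000	T	C
2	cs11_02	11350000	G	C
3	cs11_03	11351000	T	C
4	cs11_04	11352000	A	C
5	cs11_05	11353000	C	T
6	cs11_06	11354000	C	T
7	cs11_07	11355000	G	A
8	cs11_08	11356000	G	A
9	cs11_09	11357000	G	A
10	cs11_10	11358000	T	C
11	cs11_11	11359000	G	A
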