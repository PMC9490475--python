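# BLK-locus regulatory regions, hg19, BED (0-based half-open), col5 = role.
# E1/E2/E3 and the R143k scan window carry the published hg19 coordinates.
# P spans a representative 13 kb promoter window and REST a representative
# distal repressor-binding window (~115 kb downstream of P): only their
# approximate placement and extent are known, so these two are synthetic.
chr8	11348000	11361000	P	promoter
chr8	11387780	11392710	E1	enhancer
chr8	11393831	11397791	E2	enhancer
chr8	11402259	11405263	E3	enhancer
chr8	11464000	11468000	REST	repressor_site
chr8	11330999	11474000	R143k	scan_window
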