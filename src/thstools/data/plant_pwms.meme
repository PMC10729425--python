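MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF WBOX_WRKY WRKY24
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.550000 0.050000 0.350000

MOTIF ABRE_BZIP ABI5
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.150000 0.100000 0.700000
 0.050000 0.850000 0.050000 0.050000

MOTIF GBOX_GBF GBF1
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.850000 0.050000

MOTIF MBS_MYB MYB10
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
 0.050000 0.850000 0.050000 0.050000
 0.250000 0.250000 0.250000 0.250000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000
 0.450000 0.050000 0.450000 0.050000

MOTIF HDZIP_HD HAT2
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.450000 0.050000 0.050000 0.450000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000

MOTIF C2H2_ZNF STZ
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.450000 0.450000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000

MOTIF GATA_BOX GATA1
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
 0.050000 0.050000 0.850000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.850000 0.050000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000

MOTIF NACBS_NAC NAC2
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
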