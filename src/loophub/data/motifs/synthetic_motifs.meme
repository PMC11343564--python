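MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF E-box
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.010000 0.970000 0.010000 0.010000
0.010000 0.970000 0.010000 0.010000
0.970000 0.010000 0.010000 0.010000
0.010000 0.970000 0.010000 0.010000
0.010000 0.010000 0.970000 0.010000
0.010000 0.010000 0.010000 0.970000
0.010000 0.010000 0.970000 0.010000
0.010000 0.010000 0.970000 0.010000

MOTIF B-box
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.010000 0.010000 0.970000 0.010000
0.010000 0.010000 0.010000 0.970000
0.010000 0.010000 0.010000 0.970000
0.010000 0.970000 0.010000 0.010000
0.010000 0.010000 0.970000 0.010000
0.970000 0.010000 0.010000 0.010000
0.970000 0.010000 0.010000 0.010000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.010000 0.970000 0.010000 0.010000

MOTIF A-box
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.010000 0.010000 0.010000 0.970000
0.010000 0.010000 0.970000 0.010000
0.010000 0.010000 0.970000 0.010000
0.010000 0.970000 0.010000 0.010000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.970000 0.010000 0.010000 0.010000
0.485000 0.015000 0.485000 0.015000
0.015000 0.485000 0.015000 0.485000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.010000 0.010000 0.970000 0.010000

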