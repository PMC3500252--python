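H JANJ780101
D Average accessible surface area (Janin et al., 1978)
R PMID:650134
A Janin, J., Wodak, S., Levitt, M. and Maigret, B.
T Conformation of amino acid side-chains in proteins
J J. Mol. Biol. 125, 357-386 (1978)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    27.8    94.7    60.1    60.6    15.5    68.7    68.2    24.5    50.7    22.8
    27.6   103.0    33.5    25.5    51.5    42.0    45.0    34.7    55.2    23.7
//
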