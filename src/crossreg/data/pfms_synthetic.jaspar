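# Synthetic, consensus-derived count matrices (see crossreg.motif.consensus_to_pfm).
# These are stand-ins built from published IUPAC consensus patterns, not
# curated database matrices; provenance and construction are documented in
# docs/methods.md.

>SYN0001 IRF1
A  [  1  17  17  17   1   1   1  17  17  17   1 ]
C  [  1   1   1   1   1   1   1   1   1   1   1 ]
G  [ 17   1   1   1  17   1  17   1   1   1  17 ]
T  [  1   1   1   1   1  17   1   1   1   1   1 ]
>SYN0002 IRF2
A  [  1  17  17  17   5   1   1  17  17  17 ]
C  [  1   1   1   1   5   1   1   1   1   1 ]
G  [ 17   1   1   1   5   1  17   1   1   1 ]
T  [  1   1   1   1   5  17   1   1   1   1 ]
>SYN0003 IRF3
A  [  1  17  17  17   1   1  17  17  17   5   1 ]
C  [  1   1   1   1   9   9   1   1   1   5   9 ]
G  [ 17   1   1   1   9   9   1   1   1   5   1 ]
T  [  1   1   1   1   1   1   1   1   1   5   9 ]
>SYN0004 IRF7
A  [  1  17  17   9   5   1   1  17  17  17   5   1 ]
C  [  1   1   1   1   5   9   1   1   1   1   5   9 ]
G  [ 17   1   1   1   5   1  17   1   1   1   5   1 ]
T  [  1   1   1   9   5   9   1   1   1   1   5   9 ]
>SYN0005 NFKB1
A  [  1   1   1   1  17   1   1   1   1   1 ]
C  [  1   1   1   1   1   1   9  17  17  17 ]
G  [ 17  17  17  17   1   1   1   1   1   1 ]
T  [  1   1   1   1   1  17   9   1   1   1 ]
>SYN0006 NFKB2
A  [  1   1   1   1  17   9   1   1   1   1 ]
C  [  1   1   1   1   1   9   1  17  17  17 ]
G  [ 17  17  17  17   1   1   1   1   1   1 ]
T  [  1   1   1   1   1   1  17   1   1   1 ]
>SYN0007 RELA
A  [ 17   1   1  17  17  17   1   1   1   1   1 ]
C  [  1   1   1   1   1   1   1   1  17  17   1 ]
G  [  1  17  17   1   1   1   1   1   1   1  17 ]
T  [  1   1   1   1   1   1  17  17   1   1   1 ]
>SYN0008 RELB
A  [  1   1   1  17   9   1   1   1   1   1 ]
C  [  1   1   1   1   1   1   1  17  17  17 ]
G  [ 17  17  17   1   1   1   1   1   1   1 ]
T  [  1   1   1   1   9  17  17   1   1   1 ]
>SYN0009 REL
A  [  1   1   1   9  17   1   1   1   1   1 ]
C  [  1   1   1   1   1   1   1   1  17  17 ]
G  [ 17  17  17   9   1   1   1   1   1   1 ]
T  [  1   1   1   1   1  17  17  17   1   1 ]
>SYN0010 JUN
A  [  1   1  17   1   1   1  17 ]
C  [  1   1   1   9   1  17   1 ]
G  [  1  17   1   9   1   1   1 ]
T  [ 17   1   1   1  17   1   1 ]
>SYN0011 SP1
A  [  1   1   1   1   1   1   1   9   9   1 ]
C  [  1   1   1   1  17   1   1   1   1   9 ]
G  [ 17  17  17  17   1  17  17   9   9   1 ]
T  [  1   1   1   1   1   1   1   1   1   9 ]
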