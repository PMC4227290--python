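>t1
TACGTACGTACGTACGTACGTACGTACGTA
>t2
TGGCCAATTGGCCAATTGGCCAATTGGCCA
>t3
ACGTTGCAACGTTGCAACGTTGCAACGTTG
>t4
TTAACCGGTTAACCGGTTAACCGGTTAACC
>t5
CAGTCAGTCAGTCAGTCAGTCAGTCAGTCA
>t6
GTCAGTCAGTCAGTCAGTCAGTCAGTCAGT
>t7
AATTGGCCAATTGGCCAATTGGCCAATTGG
>t8
CCGGAATTCCGGAATTCCGGAATTCCGGAA
>t9
TGCATGCATGCATGCATGCATGCATGCATG
>t10
ATCGATCGATCGATCGATCGATCGATCGAT
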