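>full_silencer SMIM45 silencer LOC130067579 (ATAC-STARR-seq lymphoblastoid silent region 13815), 230 bp
TGCGCGACAACCTGGCCTTCGGCGGCCCGGAGGTCTGAGCCGACTTGCAAAGGGGATAGG
CGGGCGGCACCGGGCGCCCTCCCCCAGCCCGCCCCGCCCGCCCAGCCCGGAGACCCCCAA
GGCAGAGGGAGGCCGGCCTGTTGGCCCTCCACGCTATCCCTCTGCAGCCTGGGCCCTCCC
GACAGAGGCCCCAGGTGCGCTGGCAGTGGAGGTGGGGCACTTAGGTGCCT
>exonic_silencer SMIM45 exonic silencer segment overlapping the 68 aa ORF C-terminus, 38 bp, first codon begins at base 3
TGCGCGACAACCTGGCCTTCGGCGGCCCGGAGGTCTGA
>silencer_b SMIM45 silencer segment in the promoter of the 107 aa cistron, 192 bp
GCCGACTTGCAAAGGGGATAGGCGGGCGGCACCGGGCGCCCTCCCCCAGCCCGCCCCGCC
CGCCCAGCCCGGAGACCCCCAAGGCAGAGGGAGGCCGGCCTGTTGGCCCTCCACGCTATC
CCTCTGCAGCCTGGGCCCTCCCGACAGAGGCCCCAGGTGCGCTGGCAGTGGAGGTGGGGC
ACTTAGGTGCCT
>enhancer1 SMIM45 enhancer LOC130067578 (ATAC-STARR-seq lymphoblastoid active region 19151), 210 bp
CTAGTGGCTGAAGCACCGCCCAGGAGGAAAAACCGGCGGGGGAAGCAGGGCCGCCTGCAC
CTACCAAGATGGTGGCCGTGTTCAGGCCGGGCAGCTTGTCCAGGGGCCTCAACACCGACA
TCACAGCCGCAGGACCAACCGTTGCTCCTGCGGTGCGCGCCGATCTTTCAAACCGCCCTG
AGTCCAGCCCCTAGAGCGCGGCCTGGGGGC
>enhancer2 SMIM45 enhancer LOC127896429 (H3K4me1 hESC enhancer GRCh37_chr22:42346983-42347610), 628 bp
GAGACTCCGTCTCAAAAAAAACAAACCCTCTGTGAACTCACAGTCACCCCCCAGTCCCAC
ATATGCTGGAAAGGACCTGTCATACCTGAAGAGCCCCTAGATGGCGCAGAGGTGTCTGTG
GTGGGGGACCTAGGTCCTGAAGCCACCTCACCCAGAGGCTTTCCCCCTGCCCATCCCCAG
GTTTCTGGGAACGGATTCCCTAGGGAGGTGGTTCCTGGAAGCCTTTTCCCAGCCACGCCC
CGTGGGCCCTAGGGGGCTGCTCTCTCCCTCCTGAGAATAGCCCTCAACACGTGGCAGATA
CCTTGTCTATGGCATAGGGGGAGGGGGAGGATCCATGCTTGGGAAGGTGGACCCCACCCC
CAACGTCAGCTCTTGGCTTTGAATTCCAGCTCAGTCACTGAGAAGCTGAGGGCTCTGGGA
GAAGGAGAAGGCCAGCAGCATCACCTCTCTGCCTCATCCCAAAATGGGGTCTCAACACCA
ATCCAGCTGGGAGGACTGCAGGAAGTGATGTTGGGGCCAGCTGGAAGATGGGAGTGCTCA
ATGCCTGTGCTGGCTGTACACCAGCCAGGGGTGCTGTGGGGTAGATGAGGCAGAATGGGG
AGGGGGAGCCATTTGCAAGGGTCCTGAA
>embedded_silencer SMIM45 silencer embedded in enhancer 2 (LOC127896429 silent region 13814), 60 bp
CTAGATGGCGCAGAGGTGTCTGTGGTGGGGGACCTAGGTCCTGAAGCCACCTCACCCAGA
>enhancer3 SMIM45 enhancer LOC127896430 (NANOG hESC enhancer GRCh37_chr22:42351209-42351720), 512 bp
AGTTTCACTCTTGTTGCCCAGGCTGGAGTGCAGTGGCACAGTCGTGGCTCACTGGAACTC
CACCTCCTGGGTTCAAGCAACTCTCCTGCCTCAGCCTGCCGAGTAGTTGGGATTACAAGC
ATGTGCCACCACACCTGGCTAATTTTGTACTTTTAGTAGAGACAGGGTTTCACCATGTTG
GTCAGGCTGGTCTTGAATTCCTGACCTCAGGTGACCCATCCTCCTTGGCCTCCCAAAGTG
CTGGGATCATAGGCATGAGCCATTGGCCTGGTTGCAAAATGCTCTTTAGGCATTGTCTTG
TTAAAACTGCAAAGTACCCAGGCTGCATGCGGTGGCTCACGCCTGTAATCCCAGCACTTT
GGGAGGCCGAGGTGGGCGGATCACGAGGTCAGGAGATCAAGACCATCCTGGCTAACACGG
TGAAACCCCGTCTCTACTAAAAATACAAAAAATTAGCTGGGTGCAGTGGCGGTCACCTGC
AGTCCCAGCTACTCAGGAGGCTGAGGCAGGAG
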