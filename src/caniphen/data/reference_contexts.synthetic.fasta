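>MC1R_306ter|E synthetic amplicon context
GTAGTAAACCGCTGCTGTTCGGAGTTGTCCCTTCATCGTCCCACGTGCGAAATCGGCCAAGACAACACCA
ATAAAACTCTT
>MC1R_306ter|e synthetic amplicon context
GTAGTAAACCGCTGCTGTTCGGAGTTGTCCCTTCATCGTCTCACGTGCGAAATCGGCCAAGACAACACCA
ATAAAACTCTT
>MC1R_M264V|E synthetic amplicon context
CCTATCTCTCGGAGGAGAGGTGACGACATGGTCCGCGTAAAGTCGAGATGTATGGTATGAGCCTTGATAT
CGGTCACAGTA
>MC1R_M264V|E^m synthetic amplicon context
CCTATCTCTCGGAGGAGAGGTGACGACATGGTCCGCGTAAGGTCGAGATGTATGGTATGAGCCTTGATAT
CGGTCACAGTA
>CBD103_S54|k^y synthetic amplicon context
CCAAAAATGCATGGAATCGACAATATATCACTCATCTTAAGGGTTGCATATTGGGTACTTCTTCCTCAAA
ATGCCCCCAAGTT
>CBD103_S54|K^B synthetic amplicon context
CCAAAAATGCATGGAATCGACAATATATCACTCATCTTAATTGCATATTGGGTACTTCTTCCTCAAAATG
CCCCCAAGTT
>CBD103_S53|k^y synthetic amplicon context
TCCGCTCTGGCAGACCTCGCAAGGATCAGCACGGACAGCAGAGTGGAACCCCCAGTCTTTGTTCTATGCC
GTAACATGTCA
>CBD103_S53|K^B synthetic amplicon context
TCCGCTCTGGCAGACCTCGCAAGGATCAGCACGGACAGCACAGTGGAACCCCCAGTCTTTGTTCTATGCC
GTAACATGTCA
>ASIP_S82|A^y synthetic amplicon context
AAATTGATTCCCTAGTGTGGCGGATCGGCTTCGAACGTATTCTGCACTACAGAGAAAAATCACCCGGGAG
TAATTTTGTAT
>ASIP_S82|a^w synthetic amplicon context
AAATTGATTCCCTAGTGTGGCGGATCGGCTTCGAACGTATGCTGCACTACAGAGAAAAATCACCCGGGAG
TAATTTTGTAT
>ASIP_H83|A^y synthetic amplicon context
GAATCCCACGCCTAGGTTCGGATTAGAATTCGCGATCCTAAGGTGAGTGTTCCGGGCCAGTGCAATCGTA
TCTTGGAGGTG
>ASIP_H83|a^w synthetic amplicon context
GAATCCCACGCCTAGGTTCGGATTAGAATTCGCGATCCTAGGGTGAGTGTTCCGGGCCAGTGCAATCGTA
TCTTGGAGGTG
>ASIP_SINE|a^t synthetic amplicon context
GTTATCTGGATTCCTCGGATCCCTACTCACCACACAACCGAGGGGGGTAGGGTCGATTCACTGCAAGAGG
TACTCTTGGAAGATGGCCAGCATCTCTCACCGCTCCTTTTTAAAGCTACTACCTTAAGCTCTTCGCCTCC
CTTGTCGAAACCAGTATCGAGTGGAACGGTAAACGACAGATCACTTTAATGGGCTACGTA
>ASIP_SINE|a^w synthetic amplicon context
GTTATCTGGATTCCTCGGATCCCTACTCACCACACAACCGGTGGAACGGTAAACGACAGATCACTTTAAT
GGGCTACGTA
>ASIP_R96|a^t synthetic amplicon context
CGGATCAGTATCAACTGTTCGGGACAGGGCACACACATATCAACATAGAAGGCTGTGTGGGGAAATCCTC
CTTGGGACGTC
>ASIP_R96|a synthetic amplicon context
CGGATCAGTATCAACTGTTCGGGACAGGGCACACACATATTAACATAGAAGGCTGTGTGGGGAAATCCTC
CTTGGGACGTC
>TYRP1_Q331ter|B synthetic amplicon context
TTCCTTGGTCTCCCTACGTGTTAGGGCTTACTTGAGTAGTCGGGTGATCCGCGCTGATTGCCCCGCAGTG
TCGTGAAGCAG
>TYRP1_Q331ter|b^s synthetic amplicon context
TTCCTTGGTCTCCCTACGTGTTAGGGCTTACTTGAGTAGTTGGGTGATCCGCGCTGATTGCCCCGCAGTG
TCGTGAAGCAG
>TYRP1_345delP|B synthetic amplicon context
GTGAGCTTCGGCGATCACTTTAGCACACAGAGACGGGTGACCTCCAGTAGGTAGAACAGCGCTAGATGGA
GCAGGGTTACACT
>TYRP1_345delP|b^d synthetic amplicon context
GTGAGCTTCGGCGATCACTTTAGCACACAGAGACGGGTGACCAGTAGGTAGAACAGCGCTAGATGGAGCA
GGGTTACACT
>MLPH_157471_c.-22G>A|D synthetic amplicon context
TTACCTTTAAATGGTAAAGGGGCTTACGAAAATCCGTAATGTATGTCGATTGTATGCTTACTTACAGACA
ATTCCAGTTGG
>MLPH_157471_c.-22G>A|d synthetic amplicon context
TTACCTTTAAATGGTAAAGGGGCTTACGAAAATCCGTAATATATGTCGATTGTATGCTTACTTACAGACA
ATTCCAGTTGG
>MITF_SNP|S synthetic amplicon context
TGTCGAATGGCGATATACCTGGGCAGATTCTTTAGTAGGAAGAGAAAACACTCGTACGAAGTCGAACCTC
AAAATAATATC
>MITF_SNP|S^p synthetic amplicon context
TGTCGAATGGCGATATACCTGGGCAGATTCTTTAGTAGGAGGAGAAAACACTCGTACGAAGTCGAACCTC
AAAATAATATC
>MITF_INS|S synthetic amplicon context
TTAAACTTGAGCTCCCGAAACTTAATTGTGGGTCTCACTTTATCACAGAGCCATAAGAGTGAAGTCCACT
TTGGACGCCC
>MITF_INS|S^p synthetic amplicon context
TTAAACTTGAGCTCCCGAAACTTAATTGTGGGTCTCACTTATTTGTGATCGATACTTAGTCCAGCCCATC
TTAGAAGATGAGGCCTTTGTTCCCTGCAGTCTTCAAAACTTTGGAAGGTACGTCTTCGAGACATTGGGGC
GGAGTTCCTGGTCCAAACCATATCACAGAGCCATAAGAGTGAAGTCCACTTTGGACGCCC
>PMEL|M synthetic amplicon context
AGTGATTCTCGCCGCACCGAGGGGCCTGTGGGAGAGTTCGCAATTTCGAGACTAATTCCCGACCAGGACT
AAAACTCACGCCTTGGGTGCGCTGGCATGATTGAACGACAAAAACGGTTGTTTCAGGGGTGCGTGTCTAT
CCAACCCCCGCCCGGCGGATTCCGGTCGGCAAAACATGTTTATATAAAAGCGCCTTTCAC
>PMEL|m synthetic amplicon context
AGTGATTCTCGCCGCACCGAGGGGCCTGTGGGAGAGTTCGTCCGGTCGGCAAAACATGTTTATATAAAAG
CGCCTTTCAC
>PSMB7|H synthetic amplicon context
GAAACATTTGAAAGCGATTGCGCACGGGTAATACTGACTGGGGAGTTTCAGCTGTGCCCCCGTAGCCATC
CTAGCTTCTTC
>PSMB7|h synthetic amplicon context
GAAACATTTGAAAGCGATTGCGCACGGGTAATACTGACTGTGGAGTTTCAGCTGTGCCCCCGTAGCCATC
CTAGCTTCTTC
>FGF5|G synthetic amplicon context
ATTGATGCGCACTGGTGTGCTTTATGCCCTTTCCGTGTATGTTGGATCGGACTTGCGGTAGTGGCCCGCC
GAGGCCGGTGC
>FGF5|T synthetic amplicon context
ATTGATGCGCACTGGTGTGCTTTATGCCCTTTCCGTGTATTTTGGATCGGACTTGCGGTAGTGGCCCGCC
GAGGCCGGTGC
>RSPO2|no_Ins synthetic amplicon context
ATTGGCCATCTGGCATTCATCAAATACTTATAGACAATTCGTGATCGTAGCCTAGCGTAACGTAAGGTAA
AGCACACCCG
>RSPO2|Ins synthetic amplicon context
ATTGGCCATCTGGCATTCATCAAATACTTATAGACAATTCTTATAAATCTCCCCTACTCTTACGACAGTC
TTCAGAAGAGATGGGATGTGGCCCGCACCTATTGAACACCTGAGAGAGTGGTATTAGTCCGCAGCGTTGA
GACTCAAGCAGTTCTCAGACCATGGCACGTCTAGGTGAGGCGTCATCTTCACAGTAAACAAAGATTCGTG
ATCGTAGCCTAGCGTAACGTAAGGTAAAGCACACCCG
>KRT71|A synthetic amplicon context
TCAAAATTATACTGGAAGACTGAGTGTCAGTACATAAGCAATTCGTCAAACCGTATCACCCCCACATGGA
TTACTAGCACC
>KRT71|G synthetic amplicon context
TCAAAATTATACTGGAAGACTGAGTGTCAGTACATAAGCAGTTCGTCAAACCGTATCACCCCCACATGGA
TTACTAGCACC
>T-Box_C295G|G synthetic amplicon context
CTCCAGACCAGGGACCTTCGCTACCAGGACTAGCCCGATAGCATATTAAAAACATACCCCGAGCGCGCCG
ACTTATGGATG
>T-Box_C295G|C synthetic amplicon context
CTCCAGACCAGGGACCTTCGCTACCAGGACTAGCCCGATACCATATTAAAAACATACCCCGAGCGCGCCG
ACTTATGGATG
>BICFPJ1062878|G synthetic amplicon context
TGGGCCATACATGAACCCTATGCATGGGACTAATATAGGAGATCTGCAGACCGAAGCATACTGACGAAAG
GGCTACTCGCT
>BICFPJ1062878|A synthetic amplicon context
TGGGCCATACATGAACCCTATGCATGGGACTAATATAGGAAATCTGCAGACCGAAGCATACTGACGAAAG
GGCTACTCGCT
>IGF1R|G synthetic amplicon context
CCGGCGAACGAAGTTGGGTGCTTAGGGCTGCAAGTGGGCAGACCGCGGCTAGGCTTAGTTATATGCTCTC
CCGAAACTGCG
>IGF1R|A synthetic amplicon context
CCGGCGAACGAAGTTGGGTGCTTAGGGCTGCAAGTGGGCAAACCGCGGCTAGGCTTAGTTATATGCTCTC
CCGAAACTGCG
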