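# Default 21-marker canine phenotyping panel.
#
# One record per marker: identifier, classical coat-colour locus letter where
# applicable, trait category, marker type (SNP / microINDEL /
# intermediate_INDEL / SINE), and the allele table (symbol, nucleotide or
# presence state, dominance annotation, phenotype label).  Allele symbols with
# superscripts are written ASCII-caret style (E^m, K^B, S^p).
#
# The marker MITF_SNP distinguishes two states that the source nomenclature
# both labels "S" (dominance not clarified); the spotting-associated G state
# is stored under the symbol S^p so the two alleles of the marker remain
# distinguishable.  Coordinates are optional 1-based CanFam3.1 positions.
#
# reference_fasta points at the bundled amplicon-context file used by the
# trace caller; those sequences are SYNTHETIC stand-ins (the real amplicon
# sequences are not redistributed) with the documented insertion sizes.
version: "default-1.0"
locus_order: [E, K, A, B, D, S, M, H]
reference_fasta: reference_contexts.synthetic.fasta
markers:
  - marker_id: MC1R_306ter
    gene: MC1R
    locus: E
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "E", state: "C", dominance: dominant, phenotype: "black, brown"}
      - {name: "e", state: "T", dominance: recessive, phenotype: "red, yellow, cream, white"}
  - marker_id: MC1R_M264V
    gene: MC1R
    locus: E
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "E", state: "A", dominance: recessive, phenotype: "no melanistic mask (black, brown)"}
      - {name: "E^m", state: "G", dominance: dominant, phenotype: "melanistic mask (black, brown)"}
  - marker_id: CBD103_S54
    gene: CBD103
    locus: K
    trait_category: coat_colour
    marker_type: microINDEL
    alleles:
      - {name: "k^y", state: "GGG", dominance: recessive, phenotype: "yellow - expression of agouti alleles"}
      - {name: "K^B", state: "DelGGG", dominance: dominant, phenotype: "black, brown, blue"}
  - marker_id: CBD103_S53
    gene: CBD103
    locus: K
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "k^y", state: "G", dominance: recessive, phenotype: "yellow - expression of agouti alleles"}
      - {name: "K^B", state: "C", dominance: dominant, phenotype: "black, brown, blue"}
  - marker_id: ASIP_S82
    gene: ASIP
    locus: A
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "A^y", state: "T", dominance: dominant, phenotype: "fawn/sable"}
      - {name: "a^w", state: "G", dominance: recessive, phenotype: "wild type/agouti (black, brown)"}
  - marker_id: ASIP_H83
    gene: ASIP
    locus: A
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "A^y", state: "A", dominance: dominant, phenotype: "fawn/sable"}
      - {name: "a^w", state: "G", dominance: recessive, phenotype: "wild type/agouti (black, brown)"}
  - marker_id: ASIP_SINE
    gene: ASIP
    locus: A
    trait_category: coat_colour
    marker_type: SINE
    alleles:
      - {name: "a^t", state: "SINE", dominance: recessive, phenotype: "tan points (black, brown), tricolour"}
      - {name: "a^w", state: "no SINE", dominance: recessive, phenotype: "wild type/agouti (black, brown)"}
  - marker_id: ASIP_R96
    gene: ASIP
    locus: A
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "a^t", state: "C", dominance: recessive, phenotype: "tan points (black, brown), tricolour"}
      - {name: "a", state: "T", dominance: recessive, phenotype: "recessive black"}
  - marker_id: TYRP1_Q331ter
    gene: TYRP1
    locus: B
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "B", state: "C", dominance: dominant, phenotype: "black"}
      - {name: "b^s", state: "T", dominance: recessive, phenotype: "brown"}
  - marker_id: TYRP1_345delP
    gene: TYRP1
    locus: B
    trait_category: coat_colour
    marker_type: microINDEL
    alleles:
      - {name: "B", state: "CCT", dominance: dominant, phenotype: "black"}
      - {name: "b^d", state: "DelCCT", dominance: recessive, phenotype: "brown"}
  - marker_id: MLPH_157471_c.-22G>A
    gene: MLPH
    locus: D
    trait_category: coat_colour
    marker_type: SNP
    alleles:
      - {name: "D", state: "G", dominance: dominant, phenotype: "not diluted pigmentation"}
      - {name: "d", state: "A", dominance: recessive, phenotype: "diluted pigmentation"}
  - marker_id: MITF_SNP
    gene: MITF
    locus: S
    trait_category: coat_pattern
    marker_type: SNP
    alleles:
      - {name: "S", state: "A", dominance: unclarified, phenotype: "solid coloured, minimal white spotting"}
      - {name: "S^p", state: "G", dominance: unclarified, phenotype: "white spotting"}
  - marker_id: MITF_INS
    gene: MITF
    locus: S
    trait_category: coat_pattern
    marker_type: SINE
    alleles:
      - {name: "S", state: "no SINE", dominance: recessive, phenotype: "solid coloured, minimal white spotting"}
      - {name: "S^p", state: "SINE", dominance: recessive, phenotype: "white spotting (piebald); S/S^p pseudo irish spotting"}
  - marker_id: PMEL
    gene: PMEL
    locus: M
    trait_category: coat_pattern
    marker_type: SINE
    alleles:
      - {name: "M", state: "SINE", dominance: semi_dominant, phenotype: "merle; M/m mild merle"}
      - {name: "m", state: "no SINE", dominance: recessive, phenotype: "no merle"}
  - marker_id: PSMB7
    gene: PSMB7
    locus: H
    trait_category: coat_pattern
    marker_type: SNP
    alleles:
      - {name: "H", state: "G", dominance: dominant, phenotype: "harlequin"}
      - {name: "h", state: "T", dominance: recessive, phenotype: "no harlequin"}
  - marker_id: FGF5
    gene: FGF5
    locus: null
    trait_category: coat_structure
    marker_type: SNP
    alleles:
      - {name: "G", state: "G", dominance: dominant, phenotype: "short hair"}
      - {name: "T", state: "T", dominance: recessive, phenotype: "long hair"}
  - marker_id: RSPO2
    gene: RSPO2
    locus: null
    trait_category: coat_structure
    marker_type: intermediate_INDEL
    alleles:
      - {name: "no Ins", state: "no Ins", dominance: recessive, phenotype: "no furnishings"}
      - {name: "Ins", state: "Ins", dominance: dominant, phenotype: "furnishings"}
  - marker_id: KRT71
    gene: KRT71
    locus: null
    trait_category: coat_structure
    marker_type: SNP
    alleles:
      - {name: "A", state: "A", dominance: semi_dominant, phenotype: "smooth coat; A/G wavy coat"}
      - {name: "G", state: "G", dominance: semi_dominant, phenotype: "curly coat"}
  - marker_id: T-Box_C295G
    gene: T
    locus: null
    trait_category: tail_length
    marker_type: SNP
    alleles:
      - {name: "G", state: "G", dominance: dominant, phenotype: "bobtail"}
      - {name: "C", state: "C", dominance: recessive, phenotype: "long tail"}
  - marker_id: BICFPJ1062878
    gene: IGF2BP2
    locus: null
    trait_category: ear_shape
    marker_type: SNP
    alleles:
      - {name: "G", state: "G", dominance: unclarified, phenotype: "non drop ears"}
      - {name: "A", state: "A", dominance: unclarified, phenotype: "drop ears"}
  - marker_id: IGF1R
    gene: IGF1R
    locus: null
    trait_category: body_size
    marker_type: SNP
    coordinate: {chrom: "3", pos: 41849479}
    alleles:
      - {name: "G", state: "G", dominance: recessive, phenotype: "rather tall"}
      - {name: "A", state: "A", dominance: dominant, phenotype: "rather small"}
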