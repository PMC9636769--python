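# Curation blacklist for candidate AMGs.
#
# Categories are applied in order; the first matching category supplies the
# removal reason.  A candidate matches a category when its KO is in ko_ids or
# its functional label contains a keyword as a contiguous token sequence
# (case-insensitive).  KO sets are small curated seeds; the keyword arms
# carry the load and the whole file is meant to be edited per study.
categories:
  - category_id: dna_related_reactions
    ko_ids: [K02335, K10747, K03657, K02469]
    keywords:
      - dna polymerase
      - dna primase
      - dna helicase
      - dna ligase
      - dna topoisomerase
      - dna gyrase
      - endonuclease
      - exonuclease
      - recombinase
      - integrase
      - resolvase
      - single-stranded dna-binding
  - category_id: nucleotide_metabolism
    ko_ids: [K00560, K00525, K00526, K00943]
    keywords:
      - thymidylate synthase
      - ribonucleotide reductase
      - thymidine kinase
      - thymidylate kinase
      - dutpase
      - dcmp deaminase
      - nucleoside triphosphatase
      - deoxyribosyltransferase
  - category_id: viral_invasion
    ko_ids: []
    keywords:
      - lysozyme
      - endolysin
      - glycoside hydrolase
      - peptidase
      - cell wall hydrolase
      - holin
      - spanin
  - category_id: viral_component_modification
    ko_ids: []
    keywords:
      - glycosyl transferase
      - glycosyltransferase
      - adenylyltransferase
      - methyltransferase
  - category_id: structural_proteins
    ko_ids: []
    keywords:
      - capsid
      - portal protein
      - tail
      - baseplate
      - head protein
      - virion structural
      - scaffolding protein
      - terminase
      - neck protein
  - category_id: ribosomal_proteins
    ko_ids: []
    keywords:
      - ribosomal protein
  - category_id: transcription_translation_regulators
    ko_ids: []
    keywords:
      - transcriptional regulator
      - transcription factor
      - transcriptional repressor
      - sigma factor
      - anti-sigma
      - rna polymerase
      - translation initiation factor
      - transcription termination
  - category_id: eukaryote_specific
    ko_ids: []
    keywords:
      - histone
      - tubulin
      - actin
      - ubiquitin
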