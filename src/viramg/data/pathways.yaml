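# Seed KO -> pathway map used for AMG class assignment and by the synthetic
# community generator.  Pathway ids are descriptive slugs; top_categories
# follow the KEGG BRITE top level, so class I AMGs are those mapping to any
# pathway whose top category is "Metabolism".  Real studies should replace
# this seed with a full KO/pathway dump.
top_categories:
  nitrogen_metabolism: Metabolism
  sulfur_metabolism: Metabolism
  lipid_metabolism: Metabolism
  folate_biosynthesis: Metabolism
  carbohydrate_metabolism: Metabolism
  photosynthesis: Metabolism
  chaperones_folding: Genetic Information Processing
  signaling_proteins: Environmental Information Processing
  two_component_system: Environmental Information Processing
  defense_system: Cellular Processes

ko_pathways:
  K01915: [nitrogen_metabolism]          # glnA
  K01953: [nitrogen_metabolism]          # asnB
  K00265: [nitrogen_metabolism]          # gltB
  K00392: [sulfur_metabolism]            # sir
  K00860: [sulfur_metabolism]            # cysC
  K00059: [lipid_metabolism]             # fabG
  K02372: [lipid_metabolism]             # fabZ
  K01613: [lipid_metabolism]             # psd
  K01495: [folate_biosynthesis]          # folE
  K00287: [folate_biosynthesis]          # folA
  K13939: [folate_biosynthesis]          # folKP
  K00844: [carbohydrate_metabolism]      # HK
  K01689: [carbohydrate_metabolism]      # eno
  K05383: [photosynthesis]               # psbA-like
  K02703: [photosynthesis]               # psbA
  K04077: [chaperones_folding]           # groEL
  K04043: [chaperones_folding]           # dnaK
  K03768: [chaperones_folding]           # ppiB
  K06217: [signaling_proteins]           # phoH
  K07024: [signaling_proteins]           # mazG-like
  K07636: [two_component_system]         # phoR
  K07657: [two_component_system]         # phoB
  K07778: [two_component_system]         # desK
  K07334: [defense_system]               # higB-like antitoxin system
  K19155: [defense_system]               # abiEii
  K21498: [defense_system]               # abiGi

ko_labels:
  K01915: glutamine synthetase
  K01953: asparagine synthase
  K00265: glutamate synthase large subunit
  K00392: sulfite reductase ferredoxin
  K00860: adenylylsulfate kinase
  K00059: 3-oxoacyl-ACP reductase
  K02372: 3-hydroxyacyl-ACP dehydratase
  K01613: phosphatidylserine decarboxylase
  K01495: GTP cyclohydrolase I
  K00287: dihydrofolate reductase
  K13939: folate biosynthesis bifunctional protein
  K00844: hexokinase
  K01689: enolase
  K05383: photosystem II protein D1-like
  K02703: photosystem II P680 reaction center D1 protein
  K04077: chaperonin GroEL
  K04043: molecular chaperone DnaK
  K03768: peptidyl-prolyl cis-trans isomerase B
  K06217: phosphate starvation-inducible protein PhoH
  K07024: MazG-like nucleotide pyrophosphohydrolase family protein
  K07636: two-component system sensor histidine kinase PhoR
  K07657: two-component system response regulator PhoB
  K07778: two-component system sensor histidine kinase DesK
  K07334: toxin-antitoxin system antitoxin HigA
  K19155: abortive infection protein AbiEii
  K21498: abortive infection protein AbiGi
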