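# Fixture pathway catalog: ~16 biogeochemically relevant pathways spanning
# carbon fixation, central carbon metabolism, respiration, nitrogen, sulfur
# and trace-gas cycling. Symbols are KEGG-ortholog identifiers.
pathways:
  - id: cbb_cycle
    name: Calvin-Benson-Bassham cycle
    kind: multi_step
    key_enzymes: [K01601, K00855]        # rbcL (RuBisCO), prkB
    steps:
      - [K01601]                         # carboxylation
      - [K00927]                         # phosphoglycerate kinase
      - [K00134, K00150]                 # GAPDH
      - [K01803]                         # triose-phosphate isomerase
      - [K01623, K01624]                 # FBP aldolase
      - [K03841, K11532]                 # FBPase
      - [K00615]                         # transketolase
      - [K01807, K01808]                 # ribose-5P isomerase
      - [K01783]                         # ribulose-phosphate epimerase
      - [K00855]                         # phosphoribulokinase
    threshold: 0.5
  - id: emp_glycolysis
    name: Embden-Meyerhof-Parnas glycolysis
    kind: multi_step
    key_enzymes: [K00850]                # 6-phosphofructokinase
    steps:
      - [K00844, K00845]                 # hexokinase / glucokinase
      - [K01810]                         # glucose-6P isomerase
      - [K00850]                         # phosphofructokinase
      - [K01623, K01624]                 # FBP aldolase
      - [K01803]                         # triose-phosphate isomerase
      - [K00134, K00150]                 # GAPDH
      - [K00927]                         # phosphoglycerate kinase
      - [K01834, K15633]                 # phosphoglycerate mutase
      - [K01689]                         # enolase
      - [K00873]                         # pyruvate kinase
    threshold: 0.5
  - id: tca_cycle
    name: Tricarboxylic acid cycle
    kind: multi_step
    key_enzymes: [K01647]                # citrate synthase
    steps:
      - [K01647]
      - [K01681, K01682]                 # aconitase
      - [K00031]                         # isocitrate dehydrogenase
      - [K00164]                         # 2-oxoglutarate dehydrogenase E1
      - [K01902, K01903]                 # succinyl-CoA synthetase
      - [K00239, K00240]                 # succinate dehydrogenase
      - [K01679, K01676]                 # fumarase
      - [K00024]                         # malate dehydrogenase
    threshold: 0.5
  - id: beta_oxidation
    name: Fatty-acid beta-oxidation
    kind: multi_step
    key_enzymes: [K00632]                # 3-ketoacyl-CoA thiolase
    steps:
      - [K00249, K06445]                 # acyl-CoA dehydrogenase
      - [K01692, K01782]                 # enoyl-CoA hydratase
      - [K00022]                         # 3-hydroxyacyl-CoA dehydrogenase
      - [K00632]                         # thiolase
    threshold: 0.5
  - id: gluconeogenesis
    name: Gluconeogenesis
    kind: multi_step
    key_enzymes: [K01610]                # PEP carboxykinase
    steps:
      - [K01610]
      - [K01689]
      - [K01834, K15633]
      - [K00927]
      - [K00134, K00150]
      - [K01803]
      - [K01623, K01624]
      - [K03841, K11532]
    threshold: 0.5
  - id: cyt_aa3
    name: aa3-type cytochrome c oxidase
    kind: single_step
    gene_sets:
      - [K02274, K02275, K02276]         # coxABC
    accessory: [K02277]                  # coxD assembly subunit
  - id: cyt_cbb3
    name: cbb3-type cytochrome c oxidase
    kind: single_step
    gene_sets:
      - [K00404, K00405, K00406, K00407] # ccoNOQP
  - id: nar_nitrate_reduction
    name: Dissimilatory nitrate reductase (narGHI)
    kind: single_step
    gene_sets:
      - [K00370, K00371, K00374]
  - id: nap_nitrate_reduction
    name: Periplasmic nitrate reductase (napAB)
    kind: single_step
    gene_sets:
      - [K02567, K02568]
  - id: dnra
    name: Dissimilatory nitrate reduction to ammonium
    kind: single_step
    gene_sets:
      - [K00362, K00363]                 # nirBD
      - [K03385, K15876]                 # nrfAH
  - id: rdsr
    name: Reverse dissimilatory sulfite reductase
    kind: single_step
    gene_sets:
      - [K11180, K11181]                 # dsrAB
    accessory: [K11179]                  # dsrL-like accessory subunit
  - id: sox_complex
    name: SOX thiosulfate oxidation complex
    kind: single_step
    gene_sets:
      - [K17222, K17223, K17224, K17226, K17227]
  - id: sulfide_oxidation
    name: Sulfide:quinone oxidoreductase
    kind: single_step
    gene_sets:
      - [K17218]
  - id: co_oxidation
    name: Aerobic carbon monoxide dehydrogenase (coxLMS)
    kind: single_step
    gene_sets:
      - [K03520, K03519, K03518]
  - id: methane_oxidation
    name: Particulate methane monooxygenase (pmoCAB)
    kind: single_step
    gene_sets:
      - [K10944, K10945, K10946]
  - id: hydrogenase
    name: NAD-reducing hydrogenase large subunit
    kind: single_step
    gene_sets:
      - [K00436]
  - id: urease
    name: Urease
    kind: single_step
    gene_sets:
      - [K01428, K01429, K01430]
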