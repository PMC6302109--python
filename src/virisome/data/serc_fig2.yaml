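# Bundled community configuration: per-group replisome arrangement
# probabilities and the read-mass shares of the headline PolA + gene
# arrangements, as printed for the study community. Groups without an
# explicit arrangement list use independent per-gene presence draws.
seed: 20181214
within_group_identity: 0.90
template_divergence: 0.35
gene_identity: 0.90
read_length: 150
total_reads: 100000

groups:
  Tyr762:
    count: 289
    # joint draw reproduces Gp4 69%, RNR 40%, and Gp4-and-RNR 34%
    arrangements:
      - {genes: [Gp4-like, RNR], p: 0.34}
      - {genes: [Gp4-like], p: 0.35}
      - {genes: [RNR], p: 0.06}
      - {genes: [], p: 0.25}
    rnr_classes:
      RNR-II-RTPR: 0.45
      RNR-I-Other: 0.25
      RNR-I-CyanoSP: 0.15
      RNR-II-Other: 0.15
    accessory:
      DnaG: 0.55
  Phe762-I:
    count: 124
    genes:
      DnaB-like: 0.60
      SNF2-like: 0.13
      RNR: 0.41
    rnr_classes:
      RNR-II-RTPR: 0.50
      RNR-I-Other: 0.30
      RNR-II-Other: 0.20
    accessory:
      DnaG: 0.50
      MazG: 0.30
  Phe762-II:
    count: 42
    genes:
      RecA-like: 0.17
      SNF2-like: 0.10
      RecB-like: 0.05
      UvrD-like: 0.07
  Leu762-I:
    count: 119
    # joint draw reproduces RecB 70%, SNF2 55%, RecB-and-SNF2 54%
    arrangements:
      - {genes: [RecB-like, SNF2-like], p: 0.54}
      - {genes: [RecB-like], p: 0.16}
      - {genes: [SNF2-like], p: 0.01}
      - {genes: [], p: 0.29}
  Leu762-II:
    count: 247
    # marginals SNF2 45%, UvrD 68% with maximal co-occurrence
    arrangements:
      - {genes: [SNF2-like, UvrD-like], p: 0.45}
      - {genes: [UvrD-like], p: 0.23}
      - {genes: [], p: 0.32}

# read-mass shares of the three most abundant arrangements; remaining
# mass is split equally over all other contigs
abundance:
  - {group: Tyr762, genes: [Gp4-like], share: 0.284}
  - {group: Leu762-II, genes: [SNF2-like, UvrD-like], share: 0.164}
  - {group: Phe762-I, genes: [DnaB-like], share: 0.133}
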