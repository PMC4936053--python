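# Gene-set definitions for the census, as GENE_SYMBOL accessions.
# complete_rule "all" = every member required; an integer sets a lower
# completeness threshold.
feature_sets:
  # Respiratory complex I without the NADH dehydrogenase module (NuoEFG):
  # the 11-subunit form typical of Bacteroidales.
  - name: complex_I
    required: [NuoA, NuoB, NuoC, NuoD, NuoH, NuoI, NuoJ, NuoK, NuoL, NuoM, NuoN]
    complete_rule: all
  - name: atp_synthase
    required: [AtpA, AtpB, AtpC, AtpD, AtpE, AtpF, AtpG, AtpH]
    complete_rule: all
  # Fumarate reductase / succinate dehydrogenase, three-subunit type B.
  - name: complex_II
    required: [FrdA, FrdB, FrdC]
    complete_rule: all
  # Na+-translocating NADH:ubiquinone oxidoreductase.
  - name: nqr
    required: [NqrA, NqrB, NqrC, NqrD, NqrE, NqrF]
    complete_rule: all
  # High-affinity bd-type oxidase permitting nanaerobic growth.
  - name: cydAB
    required: [CydA, CydB]
    complete_rule: all
  # Type IX secretion system, ten core components.
  - name: T9SS
    required: [PorK, PorL, PorM, PorN, PorP, PorT, PorU, PorV, PorW, Sov]
    complete_rule: all
  - name: porXY
    required: [PorX, PorY]
    complete_rule: all
  - name: urease_cluster
    required: [UreA, UreB, UreC, UreE, UreF, UreG, UreD]
    complete_rule: all
  # Oxalate degradation: formyl-CoA transferase + oxalyl-CoA decarboxylase
  # + the adjacent permease.
  - name: oxalate_pair
    required: [Frc, Oxc, OxlT]
    complete_rule: all
  - name: superoxide_dismutase
    required: [SodA]
    complete_rule: all
  - name: catalase
    required: [KatE]
    complete_rule: all
  - name: peroxiredoxin_ahpCF
    required: [AhpC, AhpF]
    complete_rule: all
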