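# CO2-fixation pathway role tables and the phototrophy gene screen.
#
# Curated stand-in gene sets for the four screened pathways: the
# Calvin-Benson-Bassham cycle (CBB, plus an archaeal variant using the
# alternative thiazole-adenylate synthase route for RuBP regeneration), the
# reductive TCA cycle (rTCA), the Wood-Ljungdahl reductive acetyl-CoA
# pathway (WL), and the 3-hydroxypropionate bicycle (3HP). Role label sets
# accept any of the listed namespaced annotation labels as evidence.
#
# The rTCA definition encodes the conservative rule: a positive call needs
# a citrate-cleavage route -- either ATP-citrate lyase (aclAB) OR
# citryl-CoA synthetase + citryl-CoA lyase -- AND 2-oxoglutarate synthase,
# in addition to the remaining pathway roles. The
# 3-hydroxypropionate/4-hydroxybutyrate and dicarboxylate/4-hydroxybutyrate
# pathways are deliberately not defined here (thermoacidophilic-archaea
# pathways outside this screen); they can be added to a copy of this file.
pathways:
  - name: CBB
    roles:
      - {role_id: rbcL, key_marker: true, labels: ["KO:K01601", "EC:4.1.1.39"]}
      - {role_id: prk, key_marker: true, labels: ["KO:K00855", "EC:2.7.1.19"]}
      - {role_id: pgk, key_marker: false, labels: ["KO:K00927"]}
      - {role_id: gapA, key_marker: false, labels: ["KO:K00134"]}
      - {role_id: fba, key_marker: false, labels: ["KO:K01623"]}
      - {role_id: fbp, key_marker: false, labels: ["KO:K03841"]}
      - {role_id: tkt, key_marker: false, labels: ["KO:K00615"]}
      - {role_id: rpe, key_marker: false, labels: ["KO:K01783"]}
      - {role_id: rpiA, key_marker: false, labels: ["KO:K01807"]}
  - name: CBB_archaeal
    roles:
      - {role_id: rbcL, key_marker: true, labels: ["KO:K01601", "EC:4.1.1.39"]}
      - {role_id: thiazole_adenylate_synthase, key_marker: true,
         labels: ["product:thiazole-adenylate synthase"]}
      - {role_id: sbp, key_marker: true,
         labels: ["EC:3.1.3.37", "product:sedoheptulose-1,7-bisphosphatase"]}
      - {role_id: pgk, key_marker: false, labels: ["KO:K00927"]}
      - {role_id: gapA, key_marker: false, labels: ["KO:K00134"]}
      - {role_id: fba, key_marker: false, labels: ["KO:K01623"]}
      - {role_id: tkt, key_marker: false, labels: ["KO:K00615"]}
  - name: rTCA
    roles:
      - {role_id: aclA, key_marker: true, labels: ["KO:K15230"]}
      - {role_id: aclB, key_marker: true, labels: ["KO:K15231"]}
      - {role_id: ccs, key_marker: true, labels: ["KO:K15232", "KO:K15233"]}
      - {role_id: ccl, key_marker: true, labels: ["KO:K15234"]}
      - {role_id: korA, key_marker: true, labels: ["KO:K00174"]}
      - {role_id: korB, key_marker: true, labels: ["KO:K00175"]}
      - {role_id: por, key_marker: false, labels: ["KO:K00169"]}
      - {role_id: frd, key_marker: false, labels: ["KO:K00244"]}
      - {role_id: fum, key_marker: false, labels: ["KO:K01679"]}
      - {role_id: mdh, key_marker: false, labels: ["KO:K00024"]}
      - {role_id: sucCD, key_marker: false, labels: ["KO:K01902"]}
      - {role_id: idh, key_marker: false, labels: ["KO:K00031"]}
      - {role_id: acn, key_marker: false, labels: ["KO:K01681"]}
    alternative_marker_groups:
      - [["aclA", "aclB"], ["ccs", "ccl"]]
  - name: WL
    roles:
      - {role_id: codh, key_marker: true, labels: ["KO:K00198", "EC:1.2.7.4"]}
      - {role_id: acsB, key_marker: false, labels: ["KO:K14138"]}
      - {role_id: fhs, key_marker: false, labels: ["KO:K01938"]}
      - {role_id: folD, key_marker: false, labels: ["KO:K01491"]}
      - {role_id: metF, key_marker: false, labels: ["KO:K00297"]}
      - {role_id: acsE, key_marker: false, labels: ["KO:K15023"]}
      - {role_id: fdh, key_marker: false, labels: ["KO:K05299"]}
  - name: 3HP
    roles:
      - {role_id: mcr, key_marker: true, labels: ["EC:1.2.1.17", "KO:K14468"]}
      - {role_id: acc, key_marker: false, labels: ["KO:K02160"]}
      - {role_id: pcc, key_marker: false, labels: ["KO:K15052"]}
      - {role_id: mcm, key_marker: false, labels: ["KO:K01848"]}
      - {role_id: mcl, key_marker: false, labels: ["KO:K08691"]}
      - {role_id: sct, key_marker: false, labels: ["KO:K14471"]}

phototrophy:
  psII: ["KO:K02703"]          # psbA, photosystem II reaction center D1
  psI: ["KO:K02689"]           # psaA, photosystem I core
  pufL: ["KO:K08928"]          # type-II anoxygenic reaction center L
  pufM: ["KO:K08929"]          # type-II anoxygenic reaction center M
  puhA: ["KO:K13992"]          # type-II reaction center H subunit
  typeI_rc: ["KO:K08940"]      # pscA, type-I (green sulfur) reaction center
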