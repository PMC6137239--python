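# Reference EET (extracellular electron transfer) system definitions.
#
# Curated component lists for the porin-cytochrome conduits of model
# Fe(III)-reducing bacteria (Geobacter pcc, Shewanella mtrABC) and model
# Fe(II)-oxidizing bacteria (Acidithiobacillus ferrooxidans cyc2,
# Sideroxydans mtoABCD, Rhodobacter ferrooxidans foxEZY, Rhodopseudomonas
# palustris pioABC). Component ids are unique across systems. The
# gsu1999-analog periplasmic cytochrome of the Geobacter system is the one
# non-required component: genomes lacking it (e.g. Melioribacter) still
# reduce Fe(III), so its absence downgrades the call to "partial" rather
# than rejecting it.
systems:
  - name: geobacter_pcc
    source: "Geobacter sulfurreducens porin-cytochrome (pcc) conduit"
    components:
      - {component_id: gpcc_porin_ombB, role: porin, required: true}
      - {component_id: gpcc_periplasmic_omaB, role: periplasmic_ccyt, required: true}
      - {component_id: gpcc_extracellular_omcB, role: extracellular_ccyt, required: true}
      - {component_id: gpcc_periplasmic_gsu1999, role: periplasmic_ccyt, required: false}
  - name: shewanella_mtr
    source: "Shewanella oneidensis MR-1 mtrABC"
    components:
      - {component_id: mtrB_porin, role: porin, required: true}
      - {component_id: mtrA_periplasmic, role: periplasmic_ccyt, required: true}
      - {component_id: mtrC_extracellular, role: extracellular_ccyt, required: true}
  - name: cyc2
    source: "Acidithiobacillus ferrooxidans cyc2 (fused cytochrome-porin)"
    components:
      - {component_id: cyc2_fused, role: fused_cytochrome_porin, required: true}
  - name: mto
    source: "Sideroxydans lithotrophicus ES-1 mtoABCD"
    components:
      - {component_id: mtoB_porin, role: porin, required: true}
      - {component_id: mtoA_periplasmic, role: periplasmic_ccyt, required: true}
      - {component_id: mtoC_periplasmic, role: periplasmic_ccyt, required: false}
      - {component_id: mtoD_inner_membrane, role: inner_membrane_ccyt, required: false}
  - name: fox
    source: "Rhodobacter ferrooxidans SW2 foxEYZ"
    components:
      - {component_id: foxE_ccyt, role: inner_membrane_ccyt, required: true}
      - {component_id: foxY_accessory, role: inner_membrane_ccyt, required: false}
      - {component_id: foxZ_accessory, role: inner_membrane_ccyt, required: false}
  - name: pio
    source: "Rhodopseudomonas palustris TIE-1 pioABC"
    components:
      - {component_id: pioB_porin, role: porin, required: true}
      - {component_id: pioA_periplasmic, role: periplasmic_ccyt, required: true}
      - {component_id: pioC_hipip, role: periplasmic_ccyt, required: false}
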