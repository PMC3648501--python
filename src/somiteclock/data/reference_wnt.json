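{
 "model_id": "wnt",
 "provenance": {
  "tag": "reference_calibrated",
  "note": "calibrated against synthetic 120-min target profiles with the package's correlation-fitness search plus the phenotype suite as a feasibility filter",
  "burn_in_minutes": 5901.0,
  "burn_in_peak_cv": 0.00019522871286004124
 },
 "inputs": {
  "Wnt": 1.0
 },
 "parameters": {
  "Dsh_total": 0.8032909076,
  "GSK3_total": 2.523433809,
  "K_act_dsh": 0.1103122965,
  "K_act_tx_axin2": 0.8252750961,
  "K_act_tx_dll1": 0.5943287119,
  "K_act_tx_lef1": 0.5069750626,
  "K_deact_dsh": 0.1873064317,
  "K_deg_axin2_m": 0.1371864437,
  "K_deg_axin2_p": 0.2384765671,
  "K_deg_bcat": 0.1777116392,
  "K_deg_bcat_p": 0.2034086593,
  "K_deg_dll1_m": 0.3669196527,
  "K_deg_dll1_p": 0.5,
  "K_deg_lef1_m": 0.1663512696,
  "K_dephos_bcat": 0.0425007571,
  "K_phos_bcat": 0.0758304556,
  "K_wnt": 0.15,
  "Lef1_total": 2.6295299489,
  "V_act_dsh": 0.6995276472,
  "V_deact_dsh": 0.0187913451,
  "V_deg_axin2_m": 1.2635548042,
  "V_deg_axin2_p": 0.1866493872,
  "V_deg_bcat": 0.4756647988,
  "V_deg_bcat_p": 4.3101537859,
  "V_deg_dll1_m": 1.4394069022,
  "V_deg_dll1_p": 1.0,
  "V_deg_lef1_m": 1.5761770411,
  "V_dephos_bcat": 0.1711282007,
  "V_phos_bcat": 3.2576877667,
  "V_tx_axin2": 3.4446226616,
  "V_tx_dll1": 2.0352584544,
  "V_tx_lef1": 2.4747609131,
  "k_bind_gsk3": 1.6823062991,
  "k_bind_lef1": 0.428296262,
  "k_dsh_axin2": 2.8544525986,
  "k_exp_axin2": 0.3369652667,
  "k_exp_dll1": 0.0932051623,
  "k_exp_lef1": 0.2315797259,
  "k_syn_bcat": 2.6140400864,
  "k_tl_axin2": 0.1149257983,
  "k_tl_dll1": 0.3,
  "k_unbind_gsk3": 0.0553088073,
  "k_unbind_lef1": 0.4064242129
 },
 "initial_state": {
  "Dsh_active": 0.0265561008,
  "Axin2_protein": 7.0385081893,
  "GSK3_Axin2": 2.5115787911,
  "beta_catenin": 0.2513887833,
  "beta_catenin_P": 0.2429411227,
  "bcat_Lef1": 0.5667358679,
  "Dll1_protein": 1.426609025,
  "Axin2_mRNA_nuc": 3.7872271822,
  "Axin2_mRNA_cyt": 13.6576651246,
  "Lef1_mRNA_nuc": 6.7340591183,
  "Lef1_mRNA_cyt": 7.6473048785,
  "Dll1_mRNA_nuc": 13.1829659046,
  "Dll1_mRNA_cyt": 2.6746492782
 }
}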