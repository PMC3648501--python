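{
 "model_id": "combined",
 "provenance": {
  "tag": "reference_calibrated",
  "note": "calibrated against synthetic 120-min target profiles with the package's correlation-fitness search plus the phenotype suite as a feasibility filter",
  "burn_in_minutes": 5900.0,
  "burn_in_peak_cv": 0.00337459121250031
 },
 "inputs": {
  "Wnt": 1.0
 },
 "parameters": {
  "Dsh_total": 0.7,
  "GSK3_total": 2.523433809,
  "K_act_dll1": 0.3,
  "K_act_dsh": 0.1103122965,
  "K_act_tx_axin2": 0.8252750961,
  "K_act_tx_dll1": 0.8252750961,
  "K_act_tx_hes7": 1.2,
  "K_act_tx_lef1": 0.5069750626,
  "K_act_tx_lfng": 1.2,
  "K_act_tx_nkd1": 0.45,
  "K_deact_dsh": 0.1873064317,
  "K_deg_axin2_m": 0.1371864437,
  "K_deg_axin2_p": 0.2384765671,
  "K_deg_bcat": 0.1777116392,
  "K_deg_bcat_p": 0.2034086593,
  "K_deg_dll1_m": 0.3669196527,
  "K_deg_dll1_p": 0.5,
  "K_deg_hes7_m": 0.1972311116,
  "K_deg_hes7_pc": 0.9302397772,
  "K_deg_hes7_pn": 0.2369775334,
  "K_deg_lef1_m": 0.1663512696,
  "K_deg_lfng_m": 0.4624103999,
  "K_deg_lfng_p": 0.0855051973,
  "K_deg_nicd_cyt": 0.2930987418,
  "K_deg_nicd_nuc": 0.4702818555,
  "K_deg_nkd1_m": 0.2,
  "K_deg_nkd1_p": 0.2,
  "K_deg_notch": 0.5,
  "K_dephos_bcat": 0.0425007571,
  "K_phos_bcat": 0.0758304556,
  "K_rep_lfng": 0.8,
  "K_rep_tx_hes7": 0.4579051106,
  "K_rep_tx_lfng": 0.1925119743,
  "K_rep_tx_nkd1": 0.1925119743,
  "K_wnt": 0.5,
  "Lef1_total": 2.6295299489,
  "RBPj_total": 3.0,
  "V_act_dsh": 0.7477977835,
  "V_deact_dsh": 0.0076090989,
  "V_deg_axin2_m": 0.5116458389,
  "V_deg_axin2_p": 0.0755791375,
  "V_deg_bcat": 0.1926089111,
  "V_deg_bcat_p": 1.7452921251,
  "V_deg_dll1_m": 0.5828528763,
  "V_deg_dll1_p": 0.40492572,
  "V_deg_hes7_m": 0.4462862765,
  "V_deg_hes7_pc": 0.509208653,
  "V_deg_hes7_pn": 0.1447350104,
  "V_deg_lef1_m": 0.6382346232,
  "V_deg_lfng_m": 0.5148612769,
  "V_deg_lfng_p": 0.7056549644,
  "V_deg_nicd_cyt": 0.8443171447,
  "V_deg_nicd_nuc": 0.0743226275,
  "V_deg_nkd1_m": 0.85935,
  "V_deg_nkd1_p": 0.1289025,
  "V_deg_notch": 2.4590504857,
  "V_dephos_bcat": 0.0692942099,
  "V_phos_bcat": 1.3191215645,
  "V_tx_axin2": 1.3948163114,
  "V_tx_dll1": 0.824128495,
  "V_tx_hes7": 7.3921240674,
  "V_tx_lef1": 1.0020943446,
  "V_tx_lfng": 3.6206345646,
  "V_tx_nkd1": 1.7187,
  "k_bind_gsk3": 0.6812090894,
  "k_bind_lef1": 0.1734281723,
  "k_bind_nicd_dsh": 9.0,
  "k_bind_nkd1_dsh": 0.51561,
  "k_bind_rbpj": 0.1358591429,
  "k_cleave": 2.2873792492,
  "k_deg_nicd_dsh": 2.295,
  "k_deg_nkd1_dsh": 0.03825,
  "k_dsh_axin2": 1.1558412737,
  "k_exp_axin2": 0.1364459032,
  "k_exp_dll1": 0.0188705837,
  "k_exp_hes7": 0.3006272581,
  "k_exp_lef1": 0.0937725872,
  "k_exp_lfng": 0.9301851974,
  "k_exp_nkd1": 0.9301851974,
  "k_hes7_in": 0.1114809767,
  "k_hes7_out": 0.0621871505,
  "k_nicd_in": 2.5368266731,
  "k_nicd_out": 0.0183106347,
  "k_syn_bcat": 1.0584920641,
  "k_syn_notch": 1.5369065536,
  "k_tl_axin2": 0.0465364116,
  "k_tl_dll1": 0.30369429,
  "k_tl_hes7": 0.0245610394,
  "k_tl_lfng": 0.1818617374,
  "k_tl_nkd1": 0.085935,
  "k_unbind_gsk3": 0.0223959586,
  "k_unbind_lef1": 0.164571617,
  "k_unbind_nicd_dsh": 0.0429675,
  "k_unbind_nkd1_dsh": 0.0429675,
  "k_unbind_rbpj": 1.3585914286
 },
 "initial_state": {
  "Dll1_protein": 0.1918821203,
  "Notch_receptor": 0.7181521501,
  "NICD_cyt": 0.0174851486,
  "NICD_nuc": 4.4767646573,
  "NICD_RBPj": 0.9341715877,
  "Lfng_protein": 2.5748215184,
  "Hes7_protein_cyt": 1.618069935,
  "Hes7_protein_nuc": 0.352929239,
  "Lfng_mRNA_nuc": 0.4832638735,
  "Lfng_mRNA_cyt": 6.3511084044,
  "Hes7_mRNA_nuc": 7.6982048615,
  "Hes7_mRNA_cyt": 28.3053995338,
  "Dsh_active": 0.3177065023,
  "Axin2_protein": 0.6180666001,
  "GSK3_Axin2": 2.4007455817,
  "beta_catenin": 0.2920922951,
  "beta_catenin_P": 0.2362371016,
  "bcat_Lef1": 0.6167962485,
  "Axin2_mRNA_nuc": 3.6465393593,
  "Axin2_mRNA_cyt": 5.7185012824,
  "Lef1_mRNA_nuc": 6.3497010636,
  "Lef1_mRNA_cyt": 2.2891701148,
  "Dll1_mRNA_nuc": 15.5137345448,
  "Dll1_mRNA_cyt": 0.3700006714,
  "NICD_Dsh": 0.0228003533,
  "Nkd1_mRNA_nuc": 0.3888018174,
  "Nkd1_mRNA_cyt": 0.7472683347,
  "Nkd1_protein": 0.2110613343,
  "Nkd1_Dsh": 0.1738169591
 }
}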