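{
 "model_id": "notch",
 "provenance": {
  "tag": "reference_calibrated",
  "note": "calibrated against synthetic 120-min target profiles with the package's correlation-fitness search plus the phenotype suite as a feasibility filter",
  "burn_in_minutes": 5973.0,
  "burn_in_peak_cv": 1.822815924033325e-05
 },
 "inputs": {
  "dll1_signal": 1.0
 },
 "parameters": {
  "K_act_dll1": 0.5,
  "K_act_tx_hes7": 0.8,
  "K_act_tx_lfng": 0.8,
  "K_deg_dll1_p": 0.5,
  "K_deg_hes7_m": 0.1972311116,
  "K_deg_hes7_pc": 0.9302397772,
  "K_deg_hes7_pn": 0.2369775334,
  "K_deg_lfng_m": 0.4624103999,
  "K_deg_lfng_p": 0.0855051973,
  "K_deg_nicd_cyt": 0.2930987418,
  "K_deg_nicd_nuc": 0.4702818555,
  "K_deg_notch": 0.5,
  "K_rep_lfng": 1.0,
  "K_rep_tx_hes7": 0.4579051106,
  "K_rep_tx_lfng": 0.1925119743,
  "RBPj_total": 3.0,
  "V_deg_dll1_p": 0.7153809524,
  "V_deg_hes7_m": 0.5193300477,
  "V_deg_hes7_pc": 0.5925509431,
  "V_deg_hes7_pn": 0.1684238208,
  "V_deg_lfng_m": 0.5991287333,
  "V_deg_lfng_p": 0.8211496648,
  "V_deg_nicd_cyt": 0.9825067141,
  "V_deg_nicd_nuc": 0.086487028,
  "V_deg_notch": 0.7153809524,
  "V_tx_hes7": 5.7346630728,
  "V_tx_lfng": 2.8088164036,
  "k_bind_rbpj": 0.1580952381,
  "k_cleave": 1.2098886839,
  "k_exp_hes7": 0.3498309863,
  "k_exp_lfng": 1.0824288095,
  "k_hes7_in": 0.1297270923,
  "k_hes7_out": 0.0723653349,
  "k_nicd_in": 2.9520296423,
  "k_nicd_out": 0.0213075402,
  "k_syn_dll1": 0.5961507937,
  "k_syn_notch": 0.5961507937,
  "k_tl_hes7": 0.02858095,
  "k_tl_lfng": 0.2116270872,
  "k_unbind_rbpj": 1.580952381
 },
 "initial_state": {
  "Dll1_protein": 2.5,
  "Notch_receptor": 0.823987815,
  "NICD_cyt": 0.0319831649,
  "NICD_nuc": 6.5792890065,
  "NICD_RBPj": 1.1951324818,
  "Lfng_protein": 4.0416894124,
  "Hes7_protein_cyt": 1.8613973107,
  "Hes7_protein_nuc": 0.4077058139,
  "Lfng_mRNA_nuc": 0.4966770534,
  "Lfng_mRNA_cyt": 7.8537151464,
  "Hes7_mRNA_nuc": 8.8168874391,
  "Hes7_mRNA_cyt": 32.0080858806
 }
}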