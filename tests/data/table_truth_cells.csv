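preset,field,value
SATURATION_HUMAN_WT,bmax,598111
SATURATION_HUMAN_WT,pKd_radioligand,9.76
SATURATION_MOUSE_WT,bmax,21027
SATURATION_MOUSE_WT,pKd_radioligand,9.76
SATURATION_HUMAN_D432E,bmax,126377
SATURATION_HUMAN_D432E,pKd_radioligand,9.60
SATURATION_HUMAN_T433R,bmax,157442
SATURATION_HUMAN_T433R,pKd_radioligand,9.64
HUMAN_WT_LY298_ACH,pKi_agonist,4.50
HUMAN_WT_LY298_ACH,pKb_modulator,5.65
HUMAN_WT_LY298_ACH,log_alpha,2.59
HUMAN_WT_LY298_ACH,log_alpha_prime,0
HUMAN_WT_LY298_IPX,pKi_agonist,8.30
HUMAN_WT_LY298_IPX,pKb_modulator,5.65
HUMAN_WT_LY298_IPX,log_alpha,1.86
HUMAN_WT_LY298_IPX,log_alpha_prime,0
HUMAN_WT_VU154_ACH,pKi_agonist,4.40
HUMAN_WT_VU154_ACH,pKb_modulator,5.83
HUMAN_WT_VU154_ACH,log_alpha,1.61
HUMAN_WT_VU154_IPX,pKi_agonist,8.19
HUMAN_WT_VU154_IPX,pKb_modulator,5.83
HUMAN_WT_VU154_IPX,log_alpha,1.03
MOUSE_WT_LY298_ACH,pKi_agonist,4.52
MOUSE_WT_LY298_ACH,pKb_modulator,5.74
MOUSE_WT_LY298_ACH,log_alpha,1.78
MOUSE_WT_VU154_IPX,pKi_agonist,8.57
MOUSE_WT_VU154_IPX,pKb_modulator,6.07
MOUSE_WT_VU154_IPX,log_alpha,1.75
HUMAN_Q184A_LY298_IPX,pKi_agonist,8.74
HUMAN_Q184A_LY298_IPX,pKb_modulator,6.23
HUMAN_Q184A_LY298_IPX,log_alpha,1.27
HUMAN_Q184A_LY298_IPX,log_alpha_prime,-1.10
TRUPATH_HUMAN_WT_LY298_ACH,pKa_agonist,4.50
TRUPATH_HUMAN_WT_LY298_ACH,pKb_modulator,5.65
TRUPATH_HUMAN_WT_LY298_ACH,log_tau_A,2.71
TRUPATH_HUMAN_WT_LY298_ACH,log_tau_B,1.02
TRUPATH_HUMAN_WT_LY298_ACH,log_alphabeta,2.01
TRUPATH_HUMAN_WT_LY298_ACH,log_alpha,2.59
TRUPATH_HUMAN_WT_LY298_IPX,pKa_agonist,8.30
TRUPATH_HUMAN_WT_LY298_IPX,pKb_modulator,5.65
TRUPATH_HUMAN_WT_LY298_IPX,log_tau_A,1.49
TRUPATH_HUMAN_WT_LY298_IPX,log_tau_B,1.02
TRUPATH_HUMAN_WT_LY298_IPX,log_alphabeta,1.96
TRUPATH_HUMAN_WT_LY298_IPX,log_alpha,1.86
TRUPATH_HUMAN_WT_VU154_IPX,pKa_agonist,8.19
TRUPATH_HUMAN_WT_VU154_IPX,pKb_modulator,5.83
TRUPATH_HUMAN_WT_VU154_IPX,log_tau_A,1.49
TRUPATH_HUMAN_WT_VU154_IPX,log_tau_B,-0.55
TRUPATH_HUMAN_WT_VU154_IPX,log_alphabeta,0.20
TRUPATH_HUMAN_WT_VU154_IPX,log_alpha,1.03
PERK_WT_LY298_ACH,pKa_agonist,4.51
PERK_WT_LY298_ACH,pKb_modulator,4.89
PERK_WT_LY298_ACH,log_tau_A,2.96
PERK_WT_LY298_ACH,log_tau_B,1.10
PERK_WT_LY298_ACH,log_alphabeta,2.43
PERK_WT_LY298_ACH,log_alpha,1.97
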