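compound_id,name,cas,smiles,mw,acd_logp_classic,consensus_logp_acd,acd_logp_galas,acd_logd,logp_chemicalize,logd_chemicalize,chi_c18,chi_iam,logk_iam_sph
BPA,BPA,80-05-7,CC(C)(c1ccc(O)cc1)c1ccc(O)cc1,228.29,3.43,3.50,3.52,3.50,4.05,4.04,72.12,41.05,0.89
BPB,BPB,77-40-7,CCC(C)(c1ccc(O)cc1)c1ccc(O)cc1,242.32,3.96,3.93,3.91,3.93,4.49,4.49,79.12,44.60,1.13
BPC,BPC,,Cc1cc(C(C)(C)c2ccc(O)c(C)c2)ccc1O,256.34,4.35,4.25,4.18,4.25,5.07,5.07,84.86,45.77,1.22
BPE,BPE,2081-08-5,CC(c1ccc(O)cc1)c1ccc(O)cc1,214.26,3.08,3.04,3.02,3.04,3.75,3.74,67.33,38.75,0.75
BPG,BPG,127-54-8,CC(C)c1cc(C(C)(C)c2ccc(O)c(C(C)C)c2)ccc1O,312.45,6.11,5.62,5.21,5.62,6.54,6.53,107.67,53.28,N.D
BPS,BPS,80-09-1,O=S(=O)(c1ccc(O)cc1)c1ccc(O)cc1,250.28,1.83,1.81,1.80,1.74,2.32,1.98,45.20,30.23,0.09
BPBP,BPBP,1844-01-5,Oc1ccc(C(c2ccccc2)(c2ccccc2)c2ccc(O)cc2)cc1,352.43,5.84,5.40,5.18,5.40,6.31,6.31,94.81,51.91,N.D
BPS_MAE,BPS-MAE,,C=CCOc1ccc(S(=O)(=O)c2ccc(O)cc2)cc1,290.34,3.14,2.86,2.71,2.57,3.20,3.03,76.47,38.02,0.61
BPF_44,BPF 4'4',620-92-8,Oc1ccc(Cc2ccc(O)cc2)cc1,200.24,2.73,2.96,3.02,2.96,3.46,3.45,61.54,36.52,0.53
BPF_22,BPF 2'2',2467-02-9,Oc1ccccc1Cc1ccccc1O,200.24,2.73,2.96,3.02,2.96,3.46,3.33,75.46,41.18,0.68
BPF_24,BPF 2'4',2467-03-0,Oc1ccc(Cc2ccccc2O)cc1,200.24,2.73,2.96,3.02,2.96,3.46,3.45,66.48,38.22,0.59
BPP,BPP,2167-51-3,CC(C)(c1ccc(O)cc1)c1ccc(C(C)(C)c2ccc(O)cc2)cc1,346.47,6.12,5.92,5.62,5.92,6.72,6.72,101.98,55.01,2.06
BPZ,BPZ,843-55-0,Oc1ccc(C2(c3ccc(O)cc3)CCCCC2)cc1,268.36,4.53,4.25,4.07,4.25,4.92,4.91,86.51,51.17,1.36
BPAP,BPAP,1571-75-1,CC(c1ccccc1)(c1ccc(O)cc1)c1ccc(O)cc1,290.36,4.57,4.38,4.20,4.38,5.18,5.17,83.96,47.21,1.38
BPAF,BPAF,1478-61-1,Oc1ccc(C(c2ccc(O)cc2)(C(F)(F)F)C(F)(F)F)cc1,336.23,2.82,3.39,4.06,3.37,4.77,4.75,84.56,47.84,1.40
BPPH,BPPH,24038-68-4,CC(C)(c1ccc(O)c(-c2ccccc2)c1)c1ccc(O)c(-c2ccccc2)c1,380.49,6.35,5.87,5.31,5.87,7.34,7.34,108.87,56.05,N.D
BPFL,BPFL,3236-71-3,Oc1ccc(C2(c3ccc(O)cc3)c3ccccc3-c3ccccc32)cc1,350.42,4.79,5.09,5.40,5.09,5.99,5.98,89.69,49.82,1.64
BADGE,BADGE,1675-54-3,CC(C)(c1ccc(OCC2CO2)cc1)c1ccc(OCC2CO2)cc1,340.42,3.95,3.53,3.21,3.53,4.02,4.02,102.16,41.13,1.36
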