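compound_id,pic50_3t3l1,cens_3t3l1,pic50_mcf7,cens_mcf7,pic50_c6,cens_c6,pic50_hela,cens_hela,vasodilation_pct,pec50_daphnia
BPA,3.70,1,4.30,0,3.80,0,3.68,0,55.69,4.36
BPB,4.27,0,4.19,0,3.93,0,3.88,0,66.18,4.71
BPC,,0,,0,,0,,0,69.96,4.74
BPE,3.95,0,3.70,1,3.84,0,3.70,1,48.24,4.07
BPG,,0,,0,,0,,0,25.66,
BPS,3.70,1,3.70,1,3.77,0,3.52,0,24.65,3.66
BPBP,,0,,0,,0,,0,17.28,
BPS_MAE,,0,,0,,0,,0,,3.84
BPF_44,3.96,0,3.70,1,3.62,0,3.56,0,41.49,
BPF_22,,0,,0,,0,,0,,
BPF_24,,0,,0,,0,,0,,
BPP,,0,,0,,0,,0,18.61,4.93
BPZ,,0,,0,,0,,0,27.53,
BPAP,,0,,0,,0,,0,80.73,
BPAF,4.94,0,4.44,0,4.35,0,4.23,0,83.14,4.09
BPPH,,0,,0,,0,,0,26.01,
BPFL,,0,,0,,0,,0,,
BADGE,4.15,0,4.69,0,4.04,0,3.98,0,,
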