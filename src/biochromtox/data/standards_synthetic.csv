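name,t_r_min,chi_ref
theophylline,0.800,14.48
paracetamol,1.356,26.58
acetanilide,1.911,37.88
acetophenone,2.467,50.16
propiophenone,3.022,61.00
butyrophenone,3.578,73.80
valerophenone,4.133,85.67
hexanophenone,4.689,95.74
heptanophenone,5.244,108.74
octanophenone,5.800,120.38
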