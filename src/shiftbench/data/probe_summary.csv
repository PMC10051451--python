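name,molecular_weight,n_conformers,n_conformers_lower_bound,m1_h_rmsd,m1_h_md,m1_c_rmsd,m1_c_md,m2_h_rmsd,m2_h_md,m2_c_rmsd,m2_c_md,prev_h_rmsd,prev_h_md,prev_c_rmsd,prev_c_md
bicyclo[2.1.1]hexan-2-one,96,1,0,0.03,0.05,0.6,0.8,0.07,0.12,0.5,0.7,0.12,0.20,1.1,1.7
alpha-pinene,136,1,0,0.08,0.19,1.6,3.5,0.08,0.15,1.5,3.6,0.63,1.14,3.6,7.4
aquatolide,246,3,0,0.10,0.26,1.7,4.1,0.05,0.11,1.5,3.2,0.11,0.27,1.8,4.1
naupliolide,246,4,0,0.14,0.33,2.3,5.5,0.10,0.20,1.9,5.6,0.23,0.58,3.0,7.8
echinopine B,246,9,0,0.07,0.17,1.4,2.6,0.08,0.22,1.4,2.5,0.10,0.22,2.5,5.5
parthenolide,248,3,0,0.08,0.14,1.5,3.0,0.02,0.04,1.4,2.8,,,,
diepoxy-guaianolide,262,5,0,0.12,0.21,1.7,4.1,0.05,0.12,1.8,4.1,0.18,0.44,1.3,2.6
cannabicitran,258,2,0,0.11,0.17,0.9,2.2,0.07,0.17,1.0,2.2,0.12,0.31,1.1,2.0
ingenane diterpene 8,278,2,0,0.17,0.39,2.7,4.5,0.06,0.14,2.2,4.7,0.08,0.20,2.2,3.9
artemisinin,282,1,0,0.10,0.25,1.1,2.1,0.12,0.24,1.1,2.3,,,0.8,1.4
nobilistine A,317,20,0,0.14,0.25,1.7,3.6,0.12,0.25,1.5,3.5,0.27,0.65,1.6,3.1
intricarene,326,2,0,0.10,0.24,2.3,4.0,0.09,0.21,2.1,3.8,0.12,0.27,2.2,4.9
strychnine,334,3,0,0.15,0.41,1.5,4.0,0.10,0.25,1.4,3.8,0.08,0.18,1.8,6.7
holstiine,382,4,0,0.16,0.30,2.4,7.7,0.10,0.23,1.9,5.1,0.21,0.47,2.9,11.3
colchicine,399,81,0,0.10,0.21,2.1,3.8,0.11,0.20,2.2,4.0,0.16,0.25,2.3,5.0
hexacyclinol,416,23,0,0.15,0.38,2.4,7.0,0.13,0.30,2.1,5.9,0.29,0.62,4.6,9.0
homodimericin A,491,9,0,0.10,0.21,3.4,7.7,0.10,0.19,2.9,6.5,,,,
strychnobaillonine,613,12,0,0.19,0.46,3.0,10.4,0.16,0.34,2.4,6.4,0.22,0.62,2.9,6.7
sungucine,635,11,0,0.18,0.51,1.9,4.4,0.14,0.31,1.8,4.5,0.18,0.64,1.8,5.4
paclitaxel,854,157,1,0.17,0.43,2.8,7.2,0.19,0.52,2.3,6.3,,,3.7,9.1
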