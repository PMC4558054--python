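name,value,magnitude_exponent,lower_bound,upper_bound,sensitive_flag
VmaxHK,0.00023019130434782614,-4,0.0,inf,1
VfmaxPGI,0.0008124,-4,0.0,inf,1
VrmaxPGI,0.0008080000000000001,-4,0.0,inf,0
VmaxPFK,0.00040652902173913044,-4,0.0,inf,0
VmaxPGK,0.008584399999999999,-3,0.0,inf,1
VmaxPK,0.004307808,-3,0.0,inf,1
VmaxLDH,0.0012605341614906832,-3,0.0,inf,0
VmaxrLDH,0.00014000000000000001,-4,0.0,inf,0
VmaxPDH,0.000128,-4,0.0,inf,0
VmaxPC,3.2e-05,-5,0.0,inf,0
VmaxCITD,3.5999999999999994e-05,-5,0.0,inf,0
VmaxAKGDH,0.0003104,-4,0.0,inf,0
VmaxME,0.0001652,-4,0.0,inf,0
VmaxG6PDH,1.4e-05,-5,0.0,inf,0
VfmaxGlnT,3.75e-05,-5,0.0,inf,1
VrmaxGlnT,8.666666666666666e-06,-6,0.0,inf,0
VfmaxGLDH,8e-06,-6,0.0,inf,0
VrmaxGLDH,6.133333333333334e-06,-6,0.0,inf,0
VfmaxGluT,2e-06,-6,0.0,inf,0
VrmaxGluT,1.3399999999999994e-05,-5,0.0,inf,0
VmaxASTA,1.2e-05,-5,0.0,inf,0
VmaxAlaTA,0.000104,-4,0.0,inf,0
VmaxrAlaTA,7.644444444444445e-05,-5,0.0,inf,0
VmaxSDHH,1.4e-05,-5,0.0,inf,0
VmaxASN,1.2e-05,-5,0.0,inf,0
VmaxAAtoSUC,4.6500000000000005e-05,-5,0.0,inf,0
VmaxHISARGTA,1.2e-05,-5,0.0,inf,0
Vmaxresp,9.459999999999998e-05,-5,0.0,inf,1
VmaxATPase,0.0004966838000000001,-4,0.0,inf,1
Vmaxleak,2e-05,-5,0.0,inf,1
VfmaxAK,1e-05,-5,0.0,inf,1
VrmaxAK,2.3460000000000002e-05,-5,0.0,inf,1
VmaxNUCS,3.7800000000000002e-06,-6,0.0,inf,0
VmaxNADS,3.52e-07,-7,0.0,inf,0
VmaxNADPHox,0.0001146,-4,0.0,inf,0
Vmaxgrowth,0.1239664796956426,-1,0.0,inf,1
VmaxmAb,0.00014449351135325882,-4,0.0,inf,0
KmGLC_HK,1.0,0,0.0,inf,0
KmATP_ADP,4.0,0,0.0,inf,0
KdG6P,1e-07,-7,0.0,inf,1
KaAMP_ATP,0.09,-2,0.0,inf,1
alphaAMP_ATP,0.4,-1,0.0,inf,1
betaAMP_ATP,2.5,0,0.0,inf,1
KmG6P_PGI,1e-07,-7,0.0,inf,0
KdPEP_PGI,1e-08,-8,0.0,inf,0
KmF6P_rPGI,3e-06,-6,0.0,inf,0
KmF6P_PFK,3e-08,-8,0.0,inf,0
KdCIT_PFK,5e-07,-7,0.0,inf,0
KdLAC_PFK,16.0,1,0.0,inf,0
KmFBP_PGK,3e-07,-7,0.0,inf,0
KmNAD_NADH,10.0,1,0.0,inf,0
KmADP_ATP,0.25,-1,0.0,inf,1
KmPEP_PK,1e-07,-7,0.0,inf,0
KdALA_PK,1.5,0,0.0,inf,0
KaF6P_PK,3e-08,-8,0.0,inf,0
alphaF6P_PK,0.5,-1,0.0,inf,0
betaF6P_PK,2.0,0,0.0,inf,0
KmPYR_LDH,3e-07,-7,0.0,inf,0
KmNADH_NAD,0.1,-1,0.0,inf,0
KmLAC_rLDH,5.0,0,0.0,inf,0
KdPYR_rLDH,1e-07,-7,0.0,inf,0
KmPYR_PDH,1e-07,-7,0.0,inf,0
KmMAL_PDH,3e-07,-7,0.0,inf,0
KmPYR_PC,1e-07,-7,0.0,inf,0
KmCIT_CITD,5e-07,-7,0.0,inf,0
KmNADP_NADPH,2.0,0,0.0,inf,0
KmAKG_AKGDH,5e-08,-8,0.0,inf,0
KmMAL_ME,3e-07,-7,0.0,inf,0
KmG6P_G6PDH,1e-07,-7,0.0,inf,0
KmGLN_GlnT,1.0,0,0.0,inf,0
KmEGLU_rGlnT,4e-06,-6,0.0,inf,0
KmNH4_rGlnT,1.0,0,0.0,inf,0
KmEGLU_GLDH,4e-06,-6,0.0,inf,0
KmAKG_rGLDH,5e-08,-8,0.0,inf,0
KmNH4_rGLDH,2.0,0,0.0,inf,0
KmGLU_GluT,0.5,-1,0.0,inf,0
KmEGLU_rGluT,4e-06,-6,0.0,inf,0
KmASP_ASTA,0.4,-1,0.0,inf,0
KmAKG_ASTA,5e-08,-8,0.0,inf,0
KmPYR_AlaTA,1e-07,-7,0.0,inf,0
KmEGLU_AlaTA,4e-06,-6,0.0,inf,0
KmALA_rAlaTA,0.5,-1,0.0,inf,0
KmAKG_rAlaTA,5e-08,-8,0.0,inf,0
KdGLN_rAlaTA,0.3,-1,0.0,inf,0
KmSER_SDHH,1.0,0,0.0,inf,0
KmASN_ASN,1.0,0,0.0,inf,0
KmILE_AAtoSUC,1.5,0,0.0,inf,0
KmLYS_AAtoSUC,1.0,0,0.0,inf,0
KmMET_AAtoSUC,0.4,-1,0.0,inf,0
KmTHR_AAtoSUC,1.0,0,0.0,inf,0
KmVAL_AAtoSUC,1.2,0,0.0,inf,0
KmHIS_HISARGTA,0.4,-1,0.0,inf,0
KmARG_HISARGTA,1.2,0,0.0,inf,0
KmNADH,2e-07,-7,0.0,inf,1
KmATP,2e-05,-5,0.0,inf,1
KmADP_AK,5e-06,-6,0.0,inf,0
KmATP_rAK,2e-05,-5,0.0,inf,0
KmAMP_rAK,1e-06,-6,0.0,inf,0
KmR5P_NUCS,2e-08,-8,0.0,inf,0
KdATP_NUCS,2e-05,-5,0.0,inf,0
KmR5P_NADS,2e-08,-8,0.0,inf,0
KdNAD_NADS,2e-06,-6,0.0,inf,0
KmNADPH_NADP,0.5,-1,0.0,inf,0
KmATPglyc,1e-06,-6,0.0,inf,0
KmATPgrowth,1e-06,-6,0.0,inf,0
KmATPmAb,1e-06,-6,0.0,inf,0
KmG6P,2.9e-08,-8,0.0,inf,1
KmCITgrowth,5e-08,-8,0.0,inf,0
KmR5Pgrowth,4e-09,-9,0.0,inf,0
KdLacgrowth,200.0,2,0.0,inf,0
KdNH4growth,6.7,0,0.0,inf,1
Kmgrowth_GLN,0.02,-2,0.0,inf,0
KmmAb_GLN,0.01,-2,0.0,inf,0
Kmgrowth_GLU,0.02,-2,0.0,inf,0
KmmAb_GLU,0.01,-2,0.0,inf,0
Kmgrowth_ALA,0.02,-2,0.0,inf,0
KmmAb_ALA,0.01,-2,0.0,inf,0
Kmgrowth_ASP,0.02,-2,0.0,inf,0
KmmAb_ASP,0.01,-2,0.0,inf,0
Kmgrowth_ASN,0.02,-2,0.0,inf,0
KmmAb_ASN,0.01,-2,0.0,inf,0
Kmgrowth_SER,0.02,-2,0.0,inf,0
KmmAb_SER,0.01,-2,0.0,inf,0
Kmgrowth_GLY,0.02,-2,0.0,inf,0
KmmAb_GLY,0.01,-2,0.0,inf,0
Kmgrowth_ARG,0.02,-2,0.0,inf,0
KmmAb_ARG,0.01,-2,0.0,inf,0
Kmgrowth_HIS,0.02,-2,0.0,inf,0
KmmAb_HIS,0.01,-2,0.0,inf,0
Kmgrowth_ILE,0.02,-2,0.0,inf,0
KmmAb_ILE,0.01,-2,0.0,inf,0
Kmgrowth_LYS,0.02,-2,0.0,inf,0
KmmAb_LYS,0.01,-2,0.0,inf,0
Kmgrowth_MET,0.02,-2,0.0,inf,0
KmmAb_MET,0.01,-2,0.0,inf,0
Kmgrowth_PHE,0.02,-2,0.0,inf,0
KmmAb_PHE,0.01,-2,0.0,inf,0
Kmgrowth_PRO,0.02,-2,0.0,inf,0
KmmAb_PRO,0.01,-2,0.0,inf,0
Kmgrowth_THR,0.02,-2,0.0,inf,0
KmmAb_THR,0.01,-2,0.0,inf,0
Kmgrowth_TRP,0.02,-2,0.0,inf,0
KmmAb_TRP,0.01,-2,0.0,inf,0
Kmgrowth_TYR,0.02,-2,0.0,inf,0
KmmAb_TYR,0.01,-2,0.0,inf,0
Kmgrowth_VAL,0.02,-2,0.0,inf,0
KmmAb_VAL,0.01,-2,0.0,inf,0
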