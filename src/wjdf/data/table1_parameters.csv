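name,units,value_P4,value_combined,value_P9
vmaxAAtoSUC,mmol/1e6 cells/h,6.20e-4,6.20e-4,1.34e-2
vmaxAK,mmol/1e6 cells/h,1.87e-4,1.92e-4,1.94e-4
vmaxAKGDH,mmol/1e6 cells/h,1.53e-3,1.53e-3,1.53e-3
vmaxCITS,mmol/1e6 cells/h,9.42e-4,1.08e-3,1.11e-3
vmaxCS,mmol/1e6 cells/h,9.45e-4,1.08e-3,1.10e-3
vmaxgrowth,1/h,8.57e-2,6.97e-2,4.26e-2
vmaxHK,mmol/1e6 cells/h,1.58e-3,1.00e-3,7.67e-4
vmaxLDH,mmol/1e6 cells/h,7.91e-5,8.80e-5,8.88e-5
vmaxNADPHox,mmol/1e6 cells/h,4.19e-5,5.33e-5,7.81e-5
vmaxOCT,mmol/1e6 cells/h,1.35e-4,1.42e-4,9.89e-5
vmaxPDH,mmol/1e6 cells/h,1.63e-3,1.17e-3,1.08e-3
vmaxresp,mmol/1e6 cells/h,7.09e-4,7.20e-4,1.20e-3
vmaxSDH,mmol/1e6 cells/h,1.39e-3,1.39e-3,1.39e-3
vmaxASTA,mmol/1e6 cells/h,3.16e-4,3.16e-4,3.16e-4
vmaxGLN,mmol/1e6 cells/h,1.79e-1,1.79e-1,1.79e-1
KmAAtoSUCAKG,mmol/1e6 cells,1.83e-7,1.00e-7,5.21e-7
KmAAtoSUCEILE,mM,3.00e-1,3.00e-1,3.35e-1
KmAAtoSUCELEU,mM,3.00e-1,3.00e-1,9.70e-1
KmAAtoSUCELYS,mM,3.00e-1,3.00e-1,8.47e-1
KmAAtoSUCETYR,mM,1.50e-1,1.50e-1,2.31e-1
KmAAtoSUCEVAL,mM,5.00e-1,5.00e-1,2.49e-1
KmCSACCOA,mmol/1e6 cells,1.00e-8,1.00e-8,1.00e-8
KmHKEGLC,mM,4.95,5.00,6.06
alphaHKAMPATP,-,1.05,1.10,1.28
betaHKAMPATP,-,6.27e-1,1.05,1.69
KmLDHPYR,mmol/1e6 cells,1.12e-7,1.08e-7,1.04e-7
alphaLDHAMPATP,-,4.57e-1,4.65e-1,4.68e-1
betaLDHAMPATP,-,1.38e1,1.20e1,1.19e1
KmPDHPYR,mmol/1e6 cells,4.06e-7,2.00e-7,2.00e-7
KmSDHSUC,mmol/1e6 cells,3.00e-7,3.00e-7,3.00e-7
vgrowthATP,mmol/1e6 cells,1.19e-2,1.19e-2,1.19e-2
vgrowthADP,mmol/1e6 cells,1.19e-2,1.19e-2,1.19e-2
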