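name,units,value
KmAKAMP,mmol/1e6 cells,4e-06
KmAKATP,mmol/1e6 cells,2.5e-06
KmAKGDHAKG,mmol/1e6 cells,8.6e-08
KmAKGDHNAD,mmol/1e6 cells,2e-07
KmALAtALA,mmol/1e6 cells,5e-07
KmARG1ARG,mmol/1e6 cells,3e-07
KmARGtEARG,mM,0.6
KmASLASUC,mmol/1e6 cells,5e-08
KmASNASN,mmol/1e6 cells,2e-07
KmASNtEASN,mM,0.05
KmASPtEASP,mM,0.03
KmASSASP,mmol/1e6 cells,5e-07
KmASSATP,mmol/1e6 cells,2.5e-06
KmASSCTR,mmol/1e6 cells,1e-07
KmASTAGLU,mmol/1e6 cells,2e-06
KmASTAOXA,mmol/1e6 cells,1e-06
KmATPaseATP,mmol/1e6 cells,2.5e-06
KmAlaTAGLU,mmol/1e6 cells,2e-06
KmAlaTAPYR,mmol/1e6 cells,2e-07
KmCITSCIT,mmol/1e6 cells,2e-07
KmCITSNAD,mmol/1e6 cells,1e-06
KmCKADP,mmol/1e6 cells,2e-07
KmCKPCR,mmol/1e6 cells,1e-06
KmCSOXA,mmol/1e6 cells,5e-08
KmFUMaseFUM,mmol/1e6 cells,1.5e-07
KmG6PDHG6P,mmol/1e6 cells,3e-07
KmG6PDHNADP,mmol/1e6 cells,5e-07
KmGDHGLU,mmol/1e6 cells,2e-06
KmGDHNAD,mmol/1e6 cells,2e-06
KmGLNaseGLN,mmol/1e6 cells,1e-06
KmGLNtEGLN,mM,2.0
KmGLUtGLU,mmol/1e6 cells,2e-06
KmGLYtEGLY,mM,0.25
KmHISARGTAARG,mmol/1e6 cells,3e-07
KmHISARGTAEHIS,mM,0.2
KmHKATP,mmol/1e6 cells,8e-06
KmIDOETRP,mM,0.02
KmKOTEKYN,mM,0.05
KmLDHNADH,mmol/1e6 cells,1e-07
KmMDHMAL,mmol/1e6 cells,3e-07
KmMDHNAD,mmol/1e6 cells,2e-07
KmMEMAL,mmol/1e6 cells,3e-07
KmMENADP,mmol/1e6 cells,5e-07
KmNADPHoxNADPH,mmol/1e6 cells,5e-07
KmNATATP,mmol/1e6 cells,2.5e-06
KmNATR5P,mmol/1e6 cells,5e-07
KmNHGATP,mmol/1e6 cells,2.5e-06
KmNHGNAD,mmol/1e6 cells,1e-06
KmOCTORN,mmol/1e6 cells,2e-07
KmPCATP,mmol/1e6 cells,2.5e-06
KmPCPYR,mmol/1e6 cells,2e-07
KmPDHNAD,mmol/1e6 cells,1e-06
KmPFKATP,mmol/1e6 cells,2.5e-06
KmPFKF6P,mmol/1e6 cells,2e-07
KmPGIG6P,mmol/1e6 cells,3e-07
KmPGKADP,mmol/1e6 cells,2e-07
KmPGKGAP,mmol/1e6 cells,1e-07
KmPGKNAD,mmol/1e6 cells,1e-07
KmPKADP,mmol/1e6 cells,2e-07
KmPKPEP,mmol/1e6 cells,1e-06
KmPPRibPATP,mmol/1e6 cells,2.5e-06
KmPPRibPGLY,mmol/1e6 cells,5e-07
KmPPRibPR5P,mmol/1e6 cells,5e-07
KmSCOASADP,mmol/1e6 cells,2e-07
KmSCOASSCOA,mmol/1e6 cells,1e-07
KmSDHADP,mmol/1e6 cells,2e-07
KmSDHHSER,mmol/1e6 cells,5e-07
KmSERtESER,mM,0.25
KmTKR5P,mmol/1e6 cells,5e-07
KmgrowthATP,mmol/1e6 cells,8e-07
KmgrowthCIT,mmol/1e6 cells,1e-07
KmgrowthETRP,mM,0.008
KmgrowthG6P,mmol/1e6 cells,5e-08
KmgrowthR5P,mmol/1e6 cells,8e-08
KmiNOSARG,mmol/1e6 cells,3e-07
KmiNOSNADPH,mmol/1e6 cells,5e-07
KmrespADP,mmol/1e6 cells,1e-07
KmrespNADH,mmol/1e6 cells,2e-07
vmaxALAt,mmol/1e6 cells/h,0.0012
vmaxARG1,mmol/1e6 cells/h,1e-05
vmaxARGt,mmol/1e6 cells/h,1e-05
vmaxASL,mmol/1e6 cells/h,2e-05
vmaxASN,mmol/1e6 cells/h,2e-05
vmaxASNt,mmol/1e6 cells/h,2e-05
vmaxASPt,mmol/1e6 cells/h,2e-05
vmaxASS,mmol/1e6 cells/h,2e-05
vmaxATPase,mmol/1e6 cells/h,0.0032
vmaxAlaTA,mmol/1e6 cells/h,0.0003
vmaxCK,mmol/1e6 cells/h,0.0001
vmaxFUMase,mmol/1e6 cells/h,0.0014
vmaxG6PDH,mmol/1e6 cells/h,6e-06
vmaxGDH,mmol/1e6 cells/h,0.0002
vmaxGLNt,mmol/1e6 cells/h,0.0002
vmaxGLUt,mmol/1e6 cells/h,2e-05
vmaxGLYt,mmol/1e6 cells/h,2e-05
vmaxHISARGTA,mmol/1e6 cells/h,2e-05
vmaxIDO,mmol/1e6 cells/h,6e-06
vmaxKOT,mmol/1e6 cells/h,4e-06
vmaxMDH,mmol/1e6 cells/h,0.0014
vmaxME,mmol/1e6 cells/h,6e-05
vmaxNAT,mmol/1e6 cells/h,1e-07
vmaxNHG,mmol/1e6 cells/h,5e-08
vmaxPC,mmol/1e6 cells/h,4e-05
vmaxPFK,mmol/1e6 cells/h,0.0015
vmaxPGI,mmol/1e6 cells/h,0.00035
vmaxPGK,mmol/1e6 cells/h,0.0008
vmaxPK,mmol/1e6 cells/h,0.003
vmaxPPRibP,mmol/1e6 cells/h,2e-07
vmaxSCOAS,mmol/1e6 cells/h,0.0024
vmaxSDHH,mmol/1e6 cells/h,4e-05
vmaxSERt,mmol/1e6 cells/h,4e-05
vmaxTK,mmol/1e6 cells/h,3.7e-07
vmaxiNOS,mmol/1e6 cells/h,5e-06
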