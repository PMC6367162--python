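species_code,s_old,s_new,alpha1,beta1,log_alpha2,beta2,a
MOBE,0.273,0.102,-3.31,2.74,1.73,0.79,0.0163
ERCI,0.429,0.132,-1.55,1.97,0.02,1.25,0.0351
STMI,0.458,0.145,-1.78,1.46,-1.67,2.33,0.0156
SCBA,0.512,0.150,-2.03,3.10,-0.54,2.38,0.0112
ERLA,0.532,0.153,-3.15,2.86,-0.73,1.95,0.0114
PLPA,0.550,0.160,-2.18,2.43,1.45,0.84,0.0069
ERTE,0.577,0.170,-1.29,1.43,-0.07,1.36,0.0532
PLIN,0.596,0.168,-1.42,2.14,1.52,0.89,0.0380
PERE,0.627,0.173,-0.10,1.43,0.93,1.44,0.0167
EVMU,0.828,0.214,-3.86,2.36,1.58,1.30,0.0119
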