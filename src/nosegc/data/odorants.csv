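name,molecular_weight,molar_volume,beta,Da,Dm
2-acetylthiazole,127.16,120.0,1e-05,6e-06,1e-09
2-(1-mercaptoethyl)furan,128.19,133.0,0.001,6e-06,1e-09
placeholder-moderate,114.0,110.0,0.03,6e-06,1e-09
placeholder-weak,100.0,100.0,0.3,6e-06,1e-09
placeholder-volatile,88.0,95.0,3.0,6e-06,1e-09
placeholder-insoluble,72.0,90.0,30.0,6e-06,1e-09
placeholder-estimated,150.0,160.0,0.01,,
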