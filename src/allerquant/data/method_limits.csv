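allergen_name,qtm_code,ldp_cv_percent,lod_fmol,loq_fmol,lod_tafp,loq_tafp
Milk caseinate,mc-FFV,2,0.11,0.4,0.08,0.3
Milk whey,mw-VLV,4,0.13,0.4,0.16,0.5
Egg white,ew-ISQ,12,0.9,3,1.1,4
Egg yolk,ey-ATA,20,0.2,0.7,14,50
Peanut,p-TAN,11,0.10,0.3,0.14,0.5
Soybean,s-VLI,12,0.19,0.6,1.2,4
Hazelnut,h-ALP,17,0.2,0.7,0.2,0.7
Almond,a-TEE,7,0.16,0.5,0.17,0.6
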