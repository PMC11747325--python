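soc,case_count,ror,ror_low,ror_high,prr,chi2,ebgm,ebgm05,ic,ic025
Investigations,3155,7.84,7.52,8.18,5.6,12624.03,5.59,5.39,2.48,0.82
General disorders and administration site conditions,1069,0.59,0.55,0.63,0.63,274.04,0.63,0.6,-0.66,-2.32
Gastrointestinal disorders,1045,1.42,1.33,1.52,1.38,116.1,1.37,1.3,0.46,-1.21
Infections and infestations,857,1.63,1.52,1.75,1.58,192.3,1.58,1.49,0.66,-1.01
"Respiratory, thoracic and mediastinal disorders",809,1.94,1.8,2.08,1.86,336.11,1.86,1.75,0.89,-0.77
Blood and lymphatic system disorders,513,3.29,3.01,3.59,3.16,771.18,3.16,2.93,1.66,-0.01
Metabolism and nutrition disorders,393,2.17,1.96,2.4,2.12,237.3,2.12,1.95,1.08,-0.58
Nervous system disorders,307,0.42,0.37,0.47,0.44,239.09,0.44,0.4,-1.19,-2.86
Hepatobiliary disorders,216,2.8,2.45,3.2,2.76,243.79,2.76,2.46,1.46,-0.2
Cardiac disorders,209,1.12,0.98,1.29,1.12,2.65,1.12,1,0.16,-1.51
Renal and urinary disorders,181,0.94,0.81,1.09,0.94,0.7,0.94,0.83,-0.09,-1.75
Psychiatric disorders,170,0.32,0.27,0.37,0.33,243.16,0.33,0.29,-1.6,-3.26
Skin and subcutaneous tissue disorders,154,0.26,0.23,0.31,0.28,310.22,0.28,0.24,-1.86,-3.52
Musculoskeletal and connective tissue disorders,133,0.26,0.22,0.31,0.27,278.27,0.27,0.23,-1.89,-3.56
Vascular disorders,133,0.74,0.62,0.88,0.74,11.94,0.74,0.64,-0.43,-2.09
"Injury, poisoning and procedural complications",109,0.08,0.07,0.1,0.09,1093.9,0.09,0.08,-3.42,-5.09
"Congenital, familial and genetic disorders",45,1.69,1.26,2.27,1.69,12.75,1.69,1.32,0.76,-0.91
Eye disorders,37,0.2,0.14,0.28,0.2,117.74,0.2,0.16,-2.3,-3.96
Immune system disorders,29,0.25,0.17,0.36,0.25,64.66,0.25,0.19,-1.98,-3.65
Ear and labyrinth disorders,11,0.28,0.15,0.5,0.28,20.91,0.28,0.17,-1.85,-3.52
Endocrine disorders,10,0.38,0.21,0.71,0.38,9.85,0.39,0.23,-1.38,-3.04
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",9,0.02,0.01,0.05,0.02,356.02,0.02,0.01,-5.32,-6.99
Product issues,8,0.04,0.02,0.09,0.05,162.17,0.05,0.03,-4.45,-6.12
Reproductive system and breast disorders,4,0.06,0.02,0.17,0.07,53.97,0.07,0.03,-3.94,-5.61
Surgical and medical procedures,3,0.02,0.01,0.07,0.02,133.91,0.02,0.01,-5.52,-7.19
Social circumstances,1,0.02,0,0.16,0.02,43.26,0.02,0,-5.49,-7.16
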