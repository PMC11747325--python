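block,category,ae_count,ae_printed_pct,ime_count,ime_printed_pct,printed_inconsistent
Total,Total,1951,,778,,
Sex,Female,892,45.7,377,48.46,
Sex,Male,781,40.0,299,38.43,
Sex,Missing,278,14.2,102,13.11,
Age,0-6 months,361,18.50,149,19.15,
Age,6-18 months,486,24.91,251,32.26,
Age,1.5-10 years,303,15.53,162,20.82,
Age,10-18 years,4,0.21,1,0.13,
Age,18+ years,1,0.05,0,0.00,
Age,Missing,796,40.80,215,27.63,
Outcome,Death,110,5.64,100,12.85,
Outcome,Life-threatening,48,2.46,44,5.66,
Outcome,Disability,3,0.15,1,0.13,
Outcome,Hospitalization,489,25.06,289,37.15,
Outcome,Other serious events,441,22.60,277,35.60,
Outcome,Missing,860,44.08,67,8.61,
Occupation,Consumer,872,44.7,196,25.19,
Occupation,Health professional,248,12.7,118,15.17,
Occupation,Physician,784,40.2,450,57.84,
Occupation,Other healthcare professional,15,0.8,4,0.51,
Occupation,Pharmacist,20,1.0,6,0.77,
Occupation,Missing,12,0.6,4,0.51,
Country,United States,1090,55.9,279,35.86,
Country,Russian Federation,83,4.3,44,5.66,
Country,United Kingdom,63,3.2,43,5.53,
Country,Japan,60,3.1,35,4.5,
Country,Germany,50,2.6,34,4.37,
Year,2019,96,4.92,,,
Year,2020,439,25.27,,,yes
Year,2021,343,17.58,,,
Year,2022,453,23.22,,,
Year,2023,517,26.50,,,
Year,2024,103,5.28,,,
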