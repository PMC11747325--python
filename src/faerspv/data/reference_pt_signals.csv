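soc,pt,case_count,ror,ror_low,ror_high,prr,chi2,ebgm,ebgm05,ic,ic025,ime
Blood and lymphatic system disorders,Thrombocytopenia,201,12.66,11.01,14.57,12.42,2103.23,12.36,10.99,3.63,1.96,YES
Blood and lymphatic system disorders,Thrombotic microangiopathy,39,25.4,18.51,34.84,25.3,901.06,25.05,19.23,4.65,2.98,YES
Blood and lymphatic system disorders,Leukopenia,36,4.93,3.55,6.84,4.91,112.09,4.91,3.73,2.29,0.63,YES
Cardiac disorders,Tachycardia,63,5.13,4,6.57,5.1,207.55,5.09,4.14,2.35,0.68,NO
Cardiac disorders,Bradycardia,42,5.57,4.11,7.55,5.55,156.58,5.54,4.3,2.47,0.8,YES
Gastrointestinal disorders,Vomiting,488,8.14,7.43,8.92,7.78,2893.84,7.76,7.19,2.96,1.29,NO
Gastrointestinal disorders,Salivary hypersecretion,26,19.23,13.06,28.29,19.18,444.55,19.04,13.78,4.25,2.58,NO
General disorders and administration site conditions,Pyrexia,572,11.82,10.86,12.86,11.17,5302.04,11.13,10.36,3.48,1.81,NO
Hepatobiliary disorders,Hepatic function abnormal,36,6.66,4.8,9.25,6.64,172.12,6.63,5.04,2.73,1.06,NO
Hepatobiliary disorders,Hypertransaminasaemia,35,25.81,18.48,36.02,25.71,822.87,25.46,19.26,4.67,3,NO
Infections and infestations,Rhinovirus infection,50,65.94,49.75,87.38,65.6,3098.1,63.92,50.5,6,4.33,NO
Infections and infestations,Respiratory syncytial virus infection,40,22.9,16.76,31.28,22.81,826.53,22.61,17.41,4.5,2.83,NO
Infections and infestations,Respiratory tract infection,27,6.51,4.46,9.51,6.5,125.35,6.48,4.73,2.7,1.03,NO
Infections and infestations,Upper respiratory tract infection,26,3.86,2.63,5.68,3.86,54.93,3.85,2.79,1.95,0.28,NO
Infections and infestations,Viral infection,24,5.03,3.37,7.52,5.02,77.23,5.02,3.59,2.33,0.66,NO
Investigations,Aspartate aminotransferase increased,338,58.07,52.03,64.8,56.06,17881.32,54.83,50.02,5.78,4.11,NO
Investigations,Alanine aminotransferase increased,305,42.49,37.88,47.67,41.18,11768.17,40.51,36.8,5.34,3.67,NO
Investigations,Hepatic enzyme increased,245,23.22,20.44,26.38,22.66,5030.74,22.46,20.19,4.49,2.82,NO
Investigations,Platelet count decreased,166,9.75,8.36,11.38,9.6,1276.66,9.57,8.41,3.26,1.59,NO
Investigations,Troponin i increased,132,644.16,531.38,780.86,635.32,66411.99,504.9,429.8,8.98,7.31,NO
Investigations,Liver function test increased,123,29.29,24.49,35.02,28.93,3278.91,28.6,24.62,4.84,3.17,NO
Investigations,Transaminases increased,108,33.94,28.04,41.08,33.57,3367.43,33.13,28.23,5.05,3.38,NO
Investigations,Troponin increased,87,80.28,64.79,99.49,79.57,6538.19,77.1,64.43,6.27,4.6,NO
Investigations,Blood lactate dehydrogenase increased,85,50.39,40.61,62.52,49.95,3996.94,48.97,40.89,5.61,3.95,NO
Investigations,Oxygen saturation decreased,64,6.37,4.98,8.15,6.34,287.3,6.32,5.15,2.66,0.99,NO
Investigations,Body temperature increased,50,15.88,12.01,20.98,15.8,688.95,15.71,12.44,3.97,2.31,NO
Investigations,Troponin t increased,38,221.91,159.13,309.46,221.04,7636.06,202.86,153.58,7.66,5.99,NO
Investigations,Platelet count increased,37,16.77,12.13,23.18,16.7,542.71,16.6,12.66,4.05,2.39,NO
Investigations,Blood creatine phosphokinase increased,36,12.24,8.82,16.99,12.2,368.33,12.14,9.23,3.6,1.94,NO
Investigations,White blood cell count increased,36,7.55,5.44,10.49,7.53,203.35,7.51,5.71,2.91,1.24,NO
Investigations,Gamma-glutamyltransferase increased,35,14.32,10.27,19.98,14.28,429.72,14.2,10.75,3.83,2.16,NO
Investigations,Monocyte count increased,28,41.25,28.38,59.96,41.13,1078.36,40.47,29.59,5.34,3.67,NO
Investigations,Blood creatinine decreased,26,52.24,35.4,77.07,52.1,1276.05,51.04,36.86,5.67,4.01,NO
Investigations,Blood bilirubin increased,24,7.93,5.31,11.84,7.91,144.42,7.89,5.64,2.98,1.31,NO
Investigations,C-reactive protein increased,22,3.32,2.18,5.04,3.31,35.51,3.31,2.33,1.73,0.06,NO
Metabolism and nutrition disorders,Hyperkalaemia,21,4.63,3.02,7.11,4.62,59.51,4.61,3.22,2.21,0.54,YES
Nervous system disorders,Lethargy,32,4.65,3.28,6.58,4.63,91.09,4.63,3.46,2.21,0.54,NO
Psychiatric disorders,Irritability,63,10.34,8.07,13.25,10.28,525.82,10.24,8.32,3.36,1.69,NO
Renal and urinary disorders,Proteinuria,32,10.28,7.26,14.55,10.25,265.94,10.21,7.63,3.35,1.68,NO
Renal and urinary disorders,Haematuria,22,4.89,3.22,7.44,4.88,67.86,4.88,3.44,2.29,0.62,NO
"Respiratory, thoracic and mediastinal disorders",Respiratory distress,48,14.33,10.78,19.04,14.26,588.59,14.18,11.18,3.83,2.16,YES
"Respiratory, thoracic and mediastinal disorders",Rhinorrhoea,46,4.36,3.26,5.82,4.34,118.13,4.33,3.4,2.12,0.45,NO
"Respiratory, thoracic and mediastinal disorders",Respiratory failure,43,4.7,3.48,6.34,4.68,124.27,4.67,3.64,2.22,0.56,YES
"Respiratory, thoracic and mediastinal disorders",Respiratory disorder,42,9.83,7.26,13.32,9.79,330.4,9.76,7.57,3.29,1.62,NO
"Respiratory, thoracic and mediastinal disorders",Atelectasis,38,37.19,26.98,51.26,37.04,1313.03,36.51,27.91,5.19,3.52,NO
"Respiratory, thoracic and mediastinal disorders",Increased bronchial secretion,25,79.39,53.28,118.29,79.18,1869.63,76.74,54.97,6.26,4.59,NO
"Respiratory, thoracic and mediastinal disorders",Aspiration,24,17.99,12.03,26.89,17.94,381.27,17.82,12.73,4.16,2.49,YES
"Respiratory, thoracic and mediastinal disorders",Acute respiratory failure,23,7.59,5.04,11.43,7.57,130.79,7.55,5.36,2.92,1.25,YES
"Respiratory, thoracic and mediastinal disorders",Tachypnoea,22,10.8,7.1,16.43,10.78,194.41,10.74,7.56,3.42,1.76,NO
"Respiratory, thoracic and mediastinal disorders",Hypoxia,22,4.2,2.76,6.39,4.19,53.45,4.19,2.95,2.07,0.4,YES
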