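outcome,treatment_a,treatment_b,md,cri_lower,cri_upper,se,kind,source,trial_id
ahv,lonapegsomatropin,daily_somatropin,0.90,0.19,1.61,0.3622516,direct,printed,thornton2021
ahv,lonapegsomatropin,somapacitan,1.50,0.42,2.58,0.5510305,network,printed,
ahv,somapacitan,daily_somatropin,-0.60,,,0.4152210,direct,derived,miller2022
height_sds,lonapegsomatropin,daily_somatropin,0.14,0.02,0.27,0.0637767,direct,printed,thornton2021
height_sds,lonapegsomatropin,somapacitan,0.30,0.08,0.53,0.1147980,network,printed,
height_sds,somapacitan,daily_somatropin,-0.16,,,0.0954522,direct,derived,miller2022
igf1_sds,lonapegsomatropin,daily_somatropin,0.86,0.61,1.11,0.1275534,direct,printed,thornton2021
igf1_sds,somatrogon,daily_somatropin,1.57,1.28,1.86,0.1479619,direct,printed,deal2022
igf1_sds,lonapegsomatropin,somapacitan,0.83,0.41,1.25,0.2142897,network,printed,
igf1_sds,somatrogon,lonapegsomatropin,0.71,0.33,1.09,0.1953660,network,printed,
igf1_sds,somatrogon,somapacitan,1.54,1.10,1.98,0.2270580,network,printed,
igf1_sds,somapacitan,daily_somatropin,0.03,,,0.1721923,direct,derived,miller2022
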