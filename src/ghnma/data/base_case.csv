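trial_id,week,treatment,outcome,n,baseline_mean,baseline_sd,followup_mean,followup_sd,change_mean,change_sd,events,approved,provenance
thornton2021,52,lonapegsomatropin,ahv,105,,,,,11.30,2.189203,,true,derived
thornton2021,52,lonapegsomatropin,height_sds,105,-2.89,0.85,,,1.10,0.385423,,true,derived
thornton2021,52,lonapegsomatropin,igf1_sds,105,-2.08,0.88,,,2.00,0.770846,,true,derived
thornton2021,52,lonapegsomatropin,ba_ca_ratio,105,0.69,0.16,,,0.06,0.10,,true,synthetic
thornton2021,52,lonapegsomatropin,sae,105,,,,,,,3,true,synthetic
thornton2021,52,daily_somatropin,ahv,56,,,,,10.40,2.189203,,true,derived
thornton2021,52,daily_somatropin,height_sds,56,-3.00,0.90,,,0.96,0.385423,,true,derived
thornton2021,52,daily_somatropin,igf1_sds,56,-1.96,0.98,,,1.14,0.770846,,true,derived
thornton2021,52,daily_somatropin,ba_ca_ratio,56,0.70,0.14,,,0.05,0.10,,true,synthetic
thornton2021,52,daily_somatropin,sae,56,,,,,,,1,true,synthetic
deal2022,52,somatrogon,ahv,109,,,,,10.70,2.20,,true,synthetic
deal2022,52,somatrogon,height_sds,109,-2.94,1.29,,,0.97,0.42,,true,synthetic
deal2022,52,somatrogon,igf1_sds,109,-1.95,,,,2.67,1.106848,,true,derived
deal2022,52,somatrogon,ba_ca_ratio,109,,,,,0.07,0.12,,true,synthetic
deal2022,52,somatrogon,sae,109,,,,,,,4,true,synthetic
deal2022,52,daily_somatropin,ahv,115,,,,,10.40,2.20,,true,synthetic
deal2022,52,daily_somatropin,height_sds,115,-2.78,1.27,,,0.92,0.42,,true,synthetic
deal2022,52,daily_somatropin,igf1_sds,115,-1.72,,,,1.10,1.106848,,true,derived
deal2022,52,daily_somatropin,ba_ca_ratio,115,,,,,0.06,0.12,,true,synthetic
deal2022,52,daily_somatropin,sae,115,,,,,,,2,true,synthetic
miller2022,52,somapacitan,ahv,132,,,,,10.00,2.781671,,true,derived
miller2022,52,somapacitan,height_sds,132,-2.99,1.02,,,0.83,0.639458,,true,derived
miller2022,52,somapacitan,igf1_sds,132,-2.03,0.97,,,1.17,1.15356,,true,derived
miller2022,52,somapacitan,ba_ca_ratio,132,,,,,0.08,0.12,,true,synthetic
miller2022,52,somapacitan,sae,132,,,,,,,12,true,synthetic
miller2022,52,daily_somatropin,ahv,68,,,,,10.60,2.781671,,true,derived
miller2022,52,daily_somatropin,height_sds,68,-3.47,1.52,,,0.99,0.639458,,true,derived
miller2022,52,daily_somatropin,igf1_sds,68,-2.33,1.03,,,1.14,1.15356,,true,derived
miller2022,52,daily_somatropin,ba_ca_ratio,68,,,,,0.07,0.12,,true,synthetic
miller2022,52,daily_somatropin,sae,68,,,,,,,6,true,synthetic
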