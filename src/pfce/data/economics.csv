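year,treatment,water_fee,fertilizer_input,other_input,gross_income,net_income
2023,CK,580,4535,12000,61840,44725
2023,T1C1,580,22535,12000,67696,32581
2023,T1C2,580,40535,12000,69808,16693
2023,T1C3,580,58535,12000,64480,-6635
2023,T2C1,580,22535,12000,70928,35813
2023,T2C2,580,40535,12000,76640,23525
2023,T2C3,580,58535,12000,65840,-5275
2023,T3C1,580,22535,12000,65680,30565
2023,T3C2,580,40535,12000,65536,12421
2023,T3C3,580,58535,12000,62752,-8363
2024,CK,580,4535,12000,56192,39077
2024,T1C1,580,4535,12000,63056,45941
2024,T1C2,580,4535,12000,65728,48613
2024,T1C3,580,4535,12000,59616,42501
2024,T2C1,580,4535,12000,67472,50357
2024,T2C2,580,4535,12000,73440,56325
2024,T2C3,580,4535,12000,61632,44517
2024,T3C1,580,4535,12000,60800,43685
2024,T3C2,580,4535,12000,59920,42805
2024,T3C3,580,4535,12000,58640,41525
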