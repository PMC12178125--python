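year,treatment,starch,starch_sig,reducing_sugar,reducing_sugar_sig,vitamin_c,vitamin_c_sig
2023,CK,16.61,d,0.430,a,19.28,d
2023,T1C1,18.40,b,0.353,d,21.89,bc
2023,T1C2,19.08,ab,0.325,e,22.55,ab
2023,T1C3,17.46,cd,0.397,bc,20.33,cd
2023,T2C1,19.12,ab,0.317,ef,23.06,ab
2023,T2C2,19.65,a,0.300,f,23.64,a
2023,T2C3,17.90,bc,0.370,cd,21.29,c
2023,T3C1,17.71,cd,0.385,c,20.62,cd
2023,T3C2,17.03,cd,0.400,bc,20.07,cd
2023,T3C3,16.83,cd,0.420,ab,19.61,d
2024,CK,16.08,e,0.424,a,18.53,e
2024,T1C1,18.32,abc,0.337,d,21.62,b
2024,T1C2,18.70,ab,0.310,e,22.05,ab
2024,T1C3,17.27,d,0.378,c,19.75,cde
2024,T2C1,18.95,ab,0.302,ef,22.66,a
2024,T2C2,19.37,a,0.286,f,22.98,a
2024,T2C3,17.54,cd,0.352,cd,20.88,bc
2024,T3C1,17.71,bcd,0.363,bc,20.13,cd
2024,T3C2,16.85,de,0.387,abc,19.61,cde
2024,T3C3,16.47,de,0.408,a,19.25,de
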