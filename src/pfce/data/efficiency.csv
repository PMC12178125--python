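year,treatment,wue,wue_sig,pfp,pfp_sig
2023,CK,11.98,d,49.55,d
2023,T1C1,13.14,bc,54.24,bc
2023,T1C2,13.67,b,55.94,bc
2023,T1C3,12.52,cd,51.67,cd
2023,T2C1,13.84,b,56.83,b
2023,T2C2,15.11,a,61.41,a
2023,T2C3,12.76,cd,52.76,cd
2023,T3C1,12.74,cd,52.63,cd
2023,T3C2,12.72,cd,52.51,cd
2023,T3C3,12.19,d,50.28,d
2024,CK,11.26,f,45.03,f
2024,T1C1,12.74,cd,50.53,cd
2024,T1C2,13.43,bc,52.67,bc
2024,T1C3,12.34,de,47.77,ef
2024,T2C1,13.65,b,54.06,b
2024,T2C2,15.14,a,58.85,a
2024,T2C3,12.44,de,49.38,cde
2024,T3C1,12.26,de,48.72,de
2024,T3C2,12.13,de,48.01,ef
2024,T3C3,11.82,ef,46.99,ef
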