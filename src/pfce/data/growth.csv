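year,treatment,shoot_dm,shoot_dm_sig,tuber_dm,tuber_dm_sig,root_dm,root_dm_sig,plant_height,plant_height_sig,stem_diameter,stem_diameter_sig,lai,lai_sig,spad,spad_sig,yield,yield_sig
2023,CK,5.17,e,10.12,f,0.138,d,75.65,d,16.10,e,3.12,e,43.50,d,38.65,d
2023,T1C1,5.85,cd,11.82,c,0.153,abc,85.53,c,19.14,c,3.56,cd,47.98,c,42.31,bc
2023,T1C2,6.62,b,13.26,b,0.155,ab,94.67,b,19.95,bc,3.95,b,53.90,b,43.63,bc
2023,T1C3,5.53,de,10.87,de,0.145,cd,80.60,cd,17.10,de,3.34,cd,46.00,cd,40.30,cd
2023,T2C1,6.76,ab,13.60,ab,0.157,ab,99.92,ab,20.65,ab,4.05,ab,58.90,a,44.33,b
2023,T2C2,7.22,a,14.38,a,0.160,a,105.21,a,22.67,a,4.28,a,62.30,a,47.90,a
2023,T2C3,5.76,cd,11.35,d,0.151,ab,83.21,c,17.63,d,3.52,c,46.95,c,41.15,cd
2023,T3C1,5.56,de,11.00,de,0.148,bc,80.95,cd,17.13,de,3.38,cd,46.70,c,41.05,cd
2023,T3C2,5.48,de,10.51,ef,0.144,cd,78.73,cd,16.89,de,3.30,de,45.53,cd,40.96,cd
2023,T3C3,5.30,e,10.21,ef,0.143,cd,76.98,d,16.53,de,3.25,de,44.93,cd,39.22,d
2024,CK,4.56,e,9.27,e,0.134,d,71.98,f,15.72,e,2.99,e,40.23,e,35.12,f
2024,T1C1,5.22,cd,11.06,c,0.152,abc,83.27,c,18.88,c,3.47,c,45.43,c,39.41,cd
2024,T1C2,5.93,b,12.51,b,0.154,ab,90.91,b,19.67,bc,3.83,b,51.78,b,41.08,bc
2024,T1C3,4.94,d,9.93,de,0.144,bc,77.09,def,16.91,d,3.22,d,43.26,cd,37.26,ef
2024,T2C1,6.02,ab,12.42,ab,0.156,ab,97.26,ab,20.53,ab,3.91,ab,55.57,ab,42.17,b
2024,T2C2,6.51,a,13.74,a,0.158,a,102.77,a,22.39,a,4.18,a,58.35,a,45.90,a
2024,T2C3,5.23,cd,10.62,cd,0.149,abc,80.63,cd,17.31,cd,3.46,c,44.24,cd,38.52,cde
2024,T3C1,4.97,d,10.15,d,0.146,bc,77.45,e,17.00,cd,3.30,cd,43.85,cd,38.00,de
2024,T3C2,4.85,de,9.87,de,0.143,cd,75.68,def,16.54,de,3.17,de,42.69,cde,37.45,ef
2024,T3C3,4.75,de,9.75,de,0.142,cd,74.34,ef,16.36,de,3.14,de,41.85,de,36.65,ef
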