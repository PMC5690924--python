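patient_id,ptv_cc,total_dose_gy,n_fractions,r100,r50,r50_band_low,r50_band_high,d2cm_pct,d2cm_band_low,d2cm_band_high,lung_v20_pct,lung_v5_pct,lung_d1000cc_gy,cord_d035cc_gy,rib_dmax_gy,rib_d1cc_gy,rib_d5cc_gy,rib_d10cc_gy,iso_to_rib_cm
1,11.1,54,3,1.19,5.2,5.0,5.9,52.2,50.0,58.0,3.6,13.3,1.1,3.0,41.8,30.2,21.4,12.6,5.6
2,20.1,54,3,1.32,4.9,4.6,5.7,60.8,53.0,61.9,2.2,10.4,1.7,3.5,59.3,42.5,32.2,25.7,3.5
3,27.1,54,3,1.20,5.2,4.5,5.4,57.8,55.7,65.0,4.2,13.6,2.9,5.6,33.1,27.9,25.3,22.2,6.9
4,50.9,54,3,1.13,3.6,4.0,5.0,59.4,62.2,77.5,10.0,36.1,2.3,12.6,45.6,38.7,31.5,27.7,5.4
5,68.1,54,3,1.31,4.7,3.6,4.8,76.3,65.6,85.1,9.9,23.1,2.8,9.0,38.4,33.1,30.5,27.3,7.0
6,12.9,50,5,1.08,4.2,4.7,5.8,49.1,50.0,58.0,1.5,6.6,1.1,2.6,55.5,36.9,10.6,1.1,1.5
7,15.0,50,5,1.34,5.5,4.7,5.7,59.0,50.9,59.1,1.8,5.9,0.7,5.2,54.5,47.9,30.3,20.9,1.7
8,20.1,50,5,1.31,5.7,4.6,5.7,61.9,53.1,61.9,2.1,4.4,0.7,8.1,54.6,44.6,25.7,2.0,1.6
9,21.0,50,5,1.28,4.4,4.5,5.5,52.5,53.6,62.4,1.6,11.4,1.5,5.4,54.4,47.9,28.7,17.4,1.7
10,26.3,50,5,1.20,4.3,4.4,5.4,52.7,55.3,64.7,3.1,16.8,2.5,16.4,53.3,43.5,32.1,24.3,3.9
11,31.2,50,5,1.20,4.0,4.3,5.3,56.2,57.0,66.8,3.3,13.8,1.3,4.0,53.6,42.4,31.4,20.6,3.6
12,36.2,50,5,1.42,4.7,4.3,5.3,69.1,58.5,69.1,2.3,10.8,2.6,3.9,54.1,45.1,32.6,22.9,3.0
13,37.1,50,5,1.32,4.7,4.2,5.2,57.5,58.8,69.7,3.3,24.3,4.3,12.8,51.5,44.7,32.1,23.2,4.4
14,39.7,50,5,1.25,4.2,4.2,5.2,64.9,59.3,70.8,9.2,21.0,1.5,11.7,49.5,42.4,28.1,17.3,5.4
15,39.8,50,5,1.12,3.7,4.2,5.2,53.6,59.3,70.8,1.1,7.4,6.5,10.4,52.4,45.9,33.3,23.3,2.8
16,53.4,50,5,1.30,4.4,3.9,5.0,67.4,62.6,78.4,4.7,23.1,3.3,7.6,54.4,45.8,43.1,28.9,3.6
17,56.5,50,5,1.37,4.8,3.8,4.9,75.5,63.4,80.2,7.4,18.3,1.9,6.1,54.9,44.6,40.6,18.3,3.3
18,61.5,50,5,1.19,4.0,3.7,4.9,64.2,64.4,82.4,5.7,28.6,3.5,7.9,53.3,43.9,36.9,33.6,4.0
19,132.0,50,5,1.20,3.5,3.1,3.9,74.9,73.7,91.5,4.3,20.3,3.1,5.5,52.8,42.4,36.6,19.7,5.0
20,163.0,50,5,1.17,3.7,2.9,3.7,73.4,77.0,94.0,12.8,35.0,3.9,18.3,52.3,42.8,41.6,35.9,5.2
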