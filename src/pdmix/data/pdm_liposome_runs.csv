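# 29-run central-composite liposome synthesis study in the periodic-disturbance
# micromixer. Factors: frr (aqueous/organic flow-rate ratio, dimensionless),
# tfr (total flow rate, mL/h), both pump-rounded to 1 decimal; coded values per
# the rotatable design (alpha = 1.41). Responses: z_average_nm (DLS Z-average
# hydrodynamic diameter, nm), pdi (polydispersity index), zeta_mv (zeta
# potential, mV). Two transcription corrections applied; see
# pdm_liposome_runs.meta.json.
run_order,frr,tfr,frr_coded,tfr_coded,z_average_nm,pdi,zeta_mv
1,6.5,3.0,0,-1.41,133.50,0.185,-31.6
2,1.0,10.5,-1.41,0,190.70,0.060,-38.8
3,10.4,15.8,1,1,67.52,0.202,-23.1
4,6.5,18.0,0,1.41,66.63,0.185,-29.8
5,12.0,10.5,1.41,0,75.09,0.232,-37.9
6,10.4,5.2,1,-1,133.50,0.174,-32.1
7,2.6,5.2,-1,-1,119.40,0.223,-35.2
8,2.6,15.8,-1,1,86.48,0.217,-29.9
9,6.5,10.5,0,0,81.81,0.207,-32.3
10,6.5,3.0,0,-1.41,120.70,0.179,-24.6
11,1.0,10.5,-1.41,0,197.00,0.072,-28.5
12,10.4,15.8,1,1,62.10,0.270,-28.8
13,10.4,5.2,1,-1,120.20,0.170,-33.9
14,6.5,18.0,0,1.41,57.14,0.238,-33.8
15,12.0,10.5,1.41,0,74.14,0.245,-30.7
16,2.6,5.2,-1,-1,122.40,0.207,-31.5
17,2.6,15.8,-1,1,88.74,0.221,-36.3
18,6.5,10.5,0,0,72.23,0.230,-37.7
19,6.5,10.5,0,0,73.81,0.235,-27.6
20,6.5,3.0,0,-1.41,116.00,0.189,-26.9
21,1.0,10.5,-1.41,0,199.70,0.064,-29.6
22,10.4,15.8,1,1,52.71,0.228,-28.2
23,10.4,5.2,1,-1,110.40,0.184,-37.7
24,6.5,18.0,0,1.41,52.14,0.265,-34.4
25,12.0,10.5,1.41,0,73.80,0.247,-32.4
26,2.6,5.2,-1,-1,131.60,0.206,-36.5
27,2.6,15.8,-1,1,90.27,0.241,-30.2
28,6.5,10.5,0,0,77.18,0.223,-27.6
29,6.5,10.5,0,0,77.24,0.262,-30.1
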