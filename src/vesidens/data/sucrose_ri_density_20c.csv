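# Sucrose solution calibration table at 20 C, v1.
# Standard physical-chemistry values (ICUMSA / CRC handbook style tabulation):
# refractive index (nD, 589 nm) and density (g/mL) of aqueous sucrose
# by mass percent; sucrose_pct_wv derived as pct_ww * density.
sucrose_pct_ww,refractive_index,density_g_ml,sucrose_pct_wv
0,1.33299,0.99823,0.000
5,1.34026,1.01785,5.089
10,1.34782,1.03814,10.381
15,1.35568,1.05916,15.887
20,1.36384,1.08096,21.619
25,1.37233,1.10356,27.589
30,1.38115,1.12698,33.809
35,1.39032,1.15125,40.294
40,1.39986,1.17646,47.058
45,1.40978,1.20254,54.114
50,1.42009,1.22946,61.473
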