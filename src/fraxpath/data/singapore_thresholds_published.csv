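age,it_pct,lat_pct,uat_pct
40,1.51,0.65,1.81
45,1.95,0.85,2.34
50,2.96,1.32,3.56
55,4.94,2.26,5.93
60,8.35,3.95,10.02
65,13.07,6.51,15.68
70,19.87,10.68,23.85
75,25.67,14.99,30.80
80,28.53,18.24,34.23
85,31.66,20.81,37.99
90,31.79,21.08,38.15
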