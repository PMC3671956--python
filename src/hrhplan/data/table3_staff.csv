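region,doctors,doctors_per_100k,clinical_officers,co_per_100k,nurses,nurses_per_100k,skilled,skilled_per_100k
Bulawayo,168,29.57,-,-,2460,432.98,2628,462.55
Harare,349,23.92,20,1.37,4309,295.38,4678,320.67
Manicaland,26,1.68,3,0.19,1476,95.60,1505,97.48
Mashonaland Central,16,1.61,4,0.40,1160,116.53,1180,118.54
Mashonaland East,24,2.17,3,0.27,1215,110.08,1242,112.53
Mashonaland West,29,2.48,2,0.17,1184,101.31,1215,103.96
Masvingo,17,1.29,1,0.08,1606,121.72,1624,123.08
Matabeleland North,15,2.23,-,-,947,140.62,962,142.85
Matabeleland South,22,3.37,-,-,991,151.75,1013,155.12
Midlands,23,1.97,2,0.17,1684,143.89,1709,146.62
TOTAL,689,6.47,35,0.33,17032,159.85,17756,166.64
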