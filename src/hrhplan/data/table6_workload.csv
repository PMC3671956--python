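region,deliveries_per_100k,births_per_100k
Bulawayo,1785.68,2020.00
Harare,2201.89,2637.00
Manicaland,1916.59,3178.42
Mashonaland Central,1665.45,3240.18
Mashonaland East,1788.83,2986.36
Mashonaland West,1813.08,3296.51
Masvingo,2239.04,2977.45
Matabeleland North,1972.13,3001.73
Matabeleland South,2094.49,2925.26
Midlands,2553.20,3946.22
TOTAL,2024.89,3074.12
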