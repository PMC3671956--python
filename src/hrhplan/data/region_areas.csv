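region,land_area_km2
Bulawayo,479
Harare,960
Manicaland,36459
Mashonaland Central,28347
Mashonaland East,32230
Mashonaland West,57441
Masvingo,56566
Matabeleland North,75025
Matabeleland South,54172
Midlands,49166
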