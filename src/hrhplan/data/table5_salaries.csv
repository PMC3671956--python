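cadre,monthly_salary_usd,ratio_to_gdp_per_capita
General hand,127,2.56
Registered nurse,176,3.55
Doctor,218,4.40
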