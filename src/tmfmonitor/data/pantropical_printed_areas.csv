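name,value_mha
undisturbed_total_1990,1289.6
undisturbed_total_1995,1255.0
undisturbed_total_2000,1183.1
undisturbed_total_2005,1112.9
undisturbed_total_2010,1064.0
undisturbed_total_2015,1020.8
undisturbed_total_2020,964.4
tmf_total_1990,1289.6
tmf_total_2020,1070.9
undisturbed_central_africa_1990,223.1
undisturbed_central_africa_2020,184.7
undisturbed_southeast_africa_1990,15.7
undisturbed_southeast_africa_2020,6.4
deforestation_total,189.2
regrowth_total,29.5
degradation_total,106.5
degradation_africa,23.8
degradation_latin_america,39.3
degradation_asia_oceania,43.4
degradation_before_deforestation,88.6
degradation_short_term,90.0
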