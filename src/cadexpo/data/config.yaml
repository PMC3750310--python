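# Default exposure-assessment configuration.
# Units: ptmi ug/kg-bw/month; body_weight kg; ptdi ug/day; tobacco_conc ug Cd
# per g tobacco; cigarette_mass g tobacco per cigarette; water_conc ug/L;
# water_volume L/day; lod ug/L.
ptmi: 25.0
body_weight: 60.0
ptdi: 49.5
tobacco_conc: 1.5
cigarette_mass: 1.0
water_conc: 0.025
water_volume: 1.2
lod: 0.05
n_iterations: 100000
seed: 42
smoking_prevalence:
  total: 0.295
  male: 0.662
  female: 0.033
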