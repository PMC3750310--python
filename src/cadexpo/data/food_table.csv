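food,conc_mean,conc_std,conc_median,conc_p90,conc_ref2000,intake_mean,intake_std,intake_median,intake_p90
rice,0.023,0.031,0.009,0.09,0.008,208.5,102.6,200.0,300.0
wheat_flour,0.014,0.015,0.011,0.023,,33.3,48.0,14.3,100.0
coarse_cereal,0.006,0.007,0.006,0.02,,6.8,10.7,3.3,14.3
tuber,0.002,0.001,0.001,,0.015,7.4,11.4,1.7,24.3
pork,0.018,0.035,0.002,0.1,0.572,27.6,39.9,14.3,55.0
innard,0.278,0.607,0.001,0.006,,0.5,1.7,0.0,1.7
other_livestock,0.003,0.003,0.001,0.006,,4.7,7.2,1.7,14.3
poultry,0.002,0.001,0.001,0.003,,11.5,15.6,7.1,28.6
aquatic,0.043,0.225,0.007,0.091,0.024,25.3,31.3,14.3,50.0
egg,0.005,0.006,0.003,0.012,0.004,28.4,30.8,21.4,50.0
dairy,0.001,0.001,0.001,0.003,0.002,99.3,122.9,35.7,262.9
dry_bean,0.019,0.03,0.007,0.1,0.023,12.5,47.5,1.7,14.3
vegetable,0.025,0.05,0.005,0.17,0.026,205.3,106.7,200.0,300.0
fruit,0.001,0.002,0.001,0.003,0.002,63.9,58.3,50.0,150.0
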