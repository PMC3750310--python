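model,family,mean,median,std,p5,p95,min,max
total,lognormal,23.05,18.24,18.02,6.8,55.1,1.7,376.0
men,lognormal,28.49,22.2,23.05,7.7,69.0,1.5,457.8
women,lognormal,14.05,10.62,12.66,4.2,34.5,1.3,314.0
smokers,lognormal,32.74,25.78,25.83,9.6,78.3,2.8,556.1
nonsmokers,lognormal,13.23,9.63,12.72,3.6,34.0,1.0,356.44
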