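species,actual_percent,measured_percent,measured_sd,reported_deviation_percent
pork,20,20.44,0.3,2.18
pork,40,38.68,0.49,-3.29
pork,60,62.39,0.28,3.98
pork,80,79.62,0.48,-0.48
chicken,20,18.6,0.38,-6.99
chicken,40,41.49,0.64,3.73
chicken,60,60.08,0.51,0.13
chicken,80,80.15,0.53,-0.19
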