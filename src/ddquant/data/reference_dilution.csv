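species,actual_percent,measured_mean,measured_sd,reported_deviation_percent,detections,total_replicates
pork,0.01,0,,100,0,3
pork,0.05,0.01,0.01,80.89,1,3
pork,0.1,0.22,0.21,115.72,3,3
pork,0.2,0.32,0.02,58.28,3,3
pork,0.5,0.68,0.13,36.12,3,3
pork,0.8,0.58,0.12,-26.96,3,3
pork,1,1.13,0.02,12.68,3,3
pork,5,5.66,0.33,13.26,3,3
pork,10,9.68,0.06,-3.17,3,3
chicken,0.01,0,,-100,0,3
chicken,0.05,0,,-100,0,3
chicken,0.1,0.17,0.07,-70.88,3,3
chicken,0.2,0.32,0.13,-57.89,3,3
chicken,0.5,0.33,0.13,33.99,3,3
chicken,0.8,0.59,0.15,-25.89,3,3
chicken,1,0.98,0.04,-2.39,3,3
chicken,5,4.57,0.16,-8.52,3,3
chicken,10,10.91,0.01,9.13,3,3
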