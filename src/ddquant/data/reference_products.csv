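sample_id,pork_declared_percent,pork_measured_percent,chicken_declared_percent,chicken_measured_percent
Beef roll,0,0,0,0
Beef ball_1,0,0,0,0
Beef ball_2,19.0,31.67,0,0
Beef kebabs_1,0,0,0,0
Beef kebabs_2,0,0,0,0
Beefsteak,0,0,0,0
Minced beef,0,0,0,65.9
Beef stick,0,0,0,0
Beef slice,0,0,0,0
Veal sausage,0,0,0,0
Beef sausage,0,0,49.4,50.25
Canned beef,0,0,0,0
Dried beef jerky,LC,17.47,0,0
Dried beef floss,0,0,0,0
Cured beef,0,0,0,0
Bresaola,0,0,0,0
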