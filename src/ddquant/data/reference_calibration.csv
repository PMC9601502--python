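species,mass_fraction_percent,channel,replicate,copies_per_ul
pork,10,target,1,29.7
pork,10,target,2,31
pork,10,target,3,30.3
pork,10,target,4,31
pork,10,target,5,32.2
pork,10,target,6,31.7
pork,10,reference,1,332
pork,10,reference,2,350
pork,10,reference,3,345
pork,10,reference,4,344
pork,10,reference,5,355
pork,10,reference,6,361
pork,30,target,1,80.3
pork,30,target,2,71.1
pork,30,target,3,76.7
pork,30,target,4,77.8
pork,30,target,5,81.2
pork,30,target,6,87
pork,30,reference,1,201
pork,30,reference,2,190
pork,30,reference,3,189
pork,30,reference,4,205
pork,30,reference,5,223
pork,30,reference,6,233
pork,50,target,1,109
pork,50,target,2,121
pork,50,target,3,123
pork,50,target,4,127
pork,50,target,5,130
pork,50,target,6,140
pork,50,reference,1,122
pork,50,reference,2,130
pork,50,reference,3,136
pork,50,reference,4,143
pork,50,reference,5,141
pork,50,reference,6,158
pork,70,target,1,120
pork,70,target,2,120
pork,70,target,3,121
pork,70,target,4,122
pork,70,target,5,123
pork,70,target,6,134
pork,70,reference,1,62.8
pork,70,reference,2,64.5
pork,70,reference,3,64.6
pork,70,reference,4,65.3
pork,70,reference,5,64.2
pork,70,reference,6,71.1
pork,90,target,1,137
pork,90,target,2,137
pork,90,target,3,140
pork,90,target,4,142
pork,90,target,5,143
pork,90,target,6,164
pork,90,reference,1,18.2
pork,90,reference,2,18.5
pork,90,reference,3,19.4
pork,90,reference,4,19.7
pork,90,reference,5,20.3
pork,90,reference,6,22
chicken,10,target,1,230
chicken,10,target,2,247
chicken,10,target,3,255
chicken,10,target,4,225
chicken,10,target,5,221
chicken,10,target,6,226
chicken,10,reference,1,756
chicken,10,reference,2,792
chicken,10,reference,3,711
chicken,10,reference,4,736
chicken,10,reference,5,746
chicken,10,reference,6,831
chicken,30,target,1,281
chicken,30,target,2,282
chicken,30,target,3,272
chicken,30,target,4,286
chicken,30,target,5,221
chicken,30,target,6,247
chicken,30,reference,1,266
chicken,30,reference,2,209
chicken,30,reference,3,170
chicken,30,reference,4,265
chicken,30,reference,5,274
chicken,30,reference,6,258
chicken,50,target,1,375
chicken,50,target,2,392
chicken,50,target,3,377
chicken,50,target,4,401
chicken,50,target,5,384
chicken,50,target,6,394
chicken,50,reference,1,130.1
chicken,50,reference,2,146
chicken,50,reference,3,121
chicken,50,reference,4,144
chicken,50,reference,5,142
chicken,50,reference,6,129
chicken,70,target,1,535
chicken,70,target,2,582
chicken,70,target,3,583
chicken,70,target,4,593
chicken,70,target,5,601
chicken,70,target,6,600
chicken,70,reference,1,100
chicken,70,reference,2,106
chicken,70,reference,3,102
chicken,70,reference,4,105
chicken,70,reference,5,105
chicken,70,reference,6,99
chicken,90,target,1,581
chicken,90,target,2,591
chicken,90,target,3,596
chicken,90,target,4,632
chicken,90,target,5,638
chicken,90,target,6,591
chicken,90,reference,1,23.8
chicken,90,reference,2,22.5
chicken,90,reference,3,24.8
chicken,90,reference,4,24.3
chicken,90,reference,5,29
chicken,90,reference,6,28
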