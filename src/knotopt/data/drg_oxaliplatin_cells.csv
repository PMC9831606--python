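cell_id,dose,rheobase_pA,aps_0.1Hz,aps_1Hz,aps_3Hz,aps_10Hz
Cell 1,baseline,500,10,120,120,62
Cell 1,0.01,480,10,120,120,61
Cell 1,0.1,460,10,120,120,60
Cell 1,1,640,10,120,120,59
Cell 2,baseline,300,10,120,120,120
Cell 2,0.01,280,10,120,120,47
Cell 2,0.1,320,10,120,120,24
Cell 2,1,600,0,0,0,0
Cell 3,baseline,360,10,120,120,37
Cell 3,0.01,460,10,120,96,28
Cell 3,0.1,520,10,53,36,16
Cell 3,1,700,0,0,0,0
Cell 4,baseline,1450,10,120,120,32
Cell 4,0.01,1550,10,119,8,1
Cell 4,0.1,1650,10,105,1,1
Cell 4,1,1800,10,0,0,0
Cell 5,baseline,1800,10,120,120,48
Cell 5,0.01,2000,10,120,105,28
Cell 5,0.1,2000,10,120,90,27
Cell 5,1,2100,10,120,30,3
Cell 6,baseline,400,10,120,120,52
Cell 6,0.01,420,10,120,75,7
Cell 6,0.1,520,10,20,0,0
Cell 6,1,660,0,0,0,0
Cell 7,baseline,420,10,120,120,53
Cell 7,0.01,460,10,120,120,37
Cell 7,0.1,540,10,120,77,24
Cell 7,1,680,0,0,17,4
Cell 8,baseline,1950,10,120,120,120
Cell 8,0.01,1900,10,120,120,120
Cell 8,0.1,2000,10,120,120,120
Cell 8,1,3000,0,0,0,0
Cell 9,baseline,1250,10,120,120,57
Cell 9,0.01,1250,10,120,120,23
Cell 9,0.1,1300,10,120,93,18
Cell 9,1,1250,10,120,81,7
Cell 10,baseline,3200,10,120,120,60
Cell 10,0.01,3250,10,120,111,51
Cell 10,0.1,3250,10,120,107,40
Cell 10,1,4700,10,59,43,34
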