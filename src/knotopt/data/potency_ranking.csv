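peptide,ic50_nM
WT ProTx-II,0.3-1.7
PTx2-3258,3.8
PTx2-3128,5.0
PTx2-3127,6.9
PTx2-3361,8.6
JNJ63955918,10.0
PTx2-3260,20.8
PTx2-3066,30.8
PTx2-3259,41.8
PTx2-3067,48.3
PTx2-3064,52.6
PTx2-3065,73.9
PTx2-3063,154.0
PTx2-2955,185.0
PTx2-3126,2300.0
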