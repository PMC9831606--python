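peptide,subtype,ic50_nM
PTx2-3258,hNav1.1,5013
PTx2-3258,hNav1.2,3399
PTx2-3258,rNav1.3,14093
PTx2-3258,hNav1.4,8877
PTx2-3258,hNav1.5,38315
PTx2-3258,hNav1.6,382
PTx2-3258,hNav1.7,3.8
PTx2-3258,hNav1.8,43079
PTx2-3258,hNav1.9,59443
PTx2-3258,hERG,1861
PTx2-3127,hNav1.1,16970
PTx2-3127,hNav1.2,5040
PTx2-3127,rNav1.3,20040
PTx2-3127,hNav1.4,11530
PTx2-3127,hNav1.5,137090
PTx2-3127,hNav1.6,608
PTx2-3127,hNav1.7,6.9
PTx2-3127,hNav1.8,>150000
PTx2-3127,hNav1.9,>150000
PTx2-3127,hERG,1889
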