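subject,a,b,score
P01,7.1,86,-0.298
P02,3.3,70,-1.49
P03,8.8,70,-1.03
P04,1.1,110,0.503
P05,7.9,64,-1.42
P06,34.3,76,1.33
P07,1.2,100,0.266
P08,1.3,112,0.684
P09,3.7,75,1.49
P10,7.5,82,-0.465
P11,7.3,73,-0.991
P12,3.4,72,1.08
P13,1.3,113,1.67
P14,1.2,110,0.611
P15,1.9,76,-1.28
P16,2.7,77,-1.15
P17,0.90,109,0.492
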