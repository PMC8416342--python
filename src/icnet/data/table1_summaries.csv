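scale,grade,mean,sd,n,printed_f
pss_total,1,21.0,7.6,123,8.92
pss_total,2,19.6,6.2,110,8.92
pss_total,3,17.9,6.5,121,8.92
pss_total,4,16.6,7.0,100,8.92
gad7_total,1,6.6,5.1,123,3.10
gad7_total,2,5.5,4.3,110,3.10
gad7_total,3,5.0,4.9,121,3.10
gad7_total,4,5.0,4.9,100,3.10
phq9_total,1,5.7,4.6,123,4.89
phq9_total,2,4.3,4.5,110,4.89
phq9_total,3,4.0,4.6,121,4.89
phq9_total,4,3.5,4.6,100,4.89
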