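endemism_class,one_plot,plots_2_3,plots_4_5,plots_6,total
all,117,117,39,3,276
endemic,50,73,29,2,154
native,51,38,10,1,100
exotic,4,0,0,0,4
unidentified,12,6,0,0,18
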