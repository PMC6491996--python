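category,group1,group2
0,64,48
1,12,25
2,4,6
3,0,1
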