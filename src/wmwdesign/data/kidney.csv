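group,value
1,6.62
1,6.65
1,5.78
1,5.63
1,6.05
1,6.48
1,5.5
1,5.37
2,6.92
2,6.95
2,6.08
2,5.93
2,6.35
2,6.78
2,5.8
2,5.67
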