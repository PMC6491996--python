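category,group1,group2
normal,0.85,0.9
micro,0.1,0.075
macro,0.05,0.025
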