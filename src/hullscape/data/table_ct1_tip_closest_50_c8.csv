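category,blank,filled
0,0,46
1,9,35
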