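rank,A5-full-22,A7-full-9,A7-full-25,A13-full-16,A13-full-23,A5-full-1,A5-full-2,A13-full-25,A5-full-10,A5-full-28
1,0.00,0.00,0.00,0.00,0.00,4.24,0.00,0.00,5.10,5.39
2,0.00,0.00,0.00,0.00,0.00,4.24,4.24,4.24,5.10,5.39
3,0.00,0.00,0.00,0.00,0.00,4.24,4.24,4.24,5.10,5.39
4,0.00,0.00,0.00,0.00,0.00,4.24,4.24,4.24,5.10,5.39
5,4.24,4.24,4.24,4.24,4.24,4.24,4.58,4.58,5.10,5.39
6,4.58,4.58,4.58,4.58,4.58,4.58,4.58,4.58,5.291,6.71
7,4.58,4.58,4.58,4.58,4.58,6.24,4.58,4.58,6.48,6.93
8,5.10,5.10,5.10,5.10,5.10,6.24,6.24,6.24,6.71,6.93
9,5.39,5.39,5.39,5.39,5.39,6.48,6.71,6.71,6.71,7.28
10,6.24,6.24,6.24,6.24,6.24,6.71,6.71,6.71,7.28,8.00
query,9.27,9.27,9.27,9.27,9.27,9.90,10.15,10.15,10.39,10.44
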