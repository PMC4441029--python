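r1,r2,r3,display,verified
1,1,1,1-1-1,yes
1,1,2,1-1-2,yes
1,2,1,1-2-1,yes
2,1,1,2-1-1,yes
1,2,2,1-2-2,yes
2,1,2,2-1-2,yes
2,2,1,2-2-1,yes
1,1,3,1-1-3,no
1,3,1,1-3-1,no
3,1,1,3-1-1,no
1,2,3,1-2-3,no
3,2,1,3-2-1,no
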