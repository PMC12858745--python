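volume_percent,level_dba
0,58
25,76
50,85
75,93
100,100
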