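>LXRE_DR4
0.91	0.03	0.03	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.03	0.91
0.03	0.91	0.03	0.03
0.91	0.03	0.03	0.03
0.25	0.25	0.25	0.25
0.25	0.25	0.25	0.25
0.25	0.25	0.25	0.25
0.25	0.25	0.25	0.25
0.91	0.03	0.03	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.03	0.91
0.03	0.91	0.03	0.03
0.91	0.03	0.03	0.03
>NR_half
0.91	0.03	0.03	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.03	0.91
0.03	0.91	0.03	0.03
0.91	0.03	0.03	0.03
>NFKB
0.03	0.03	0.91	0.03
0.03	0.03	0.91	0.03
0.03	0.03	0.91	0.03
0.455	0.045	0.455	0.045
0.25	0.25	0.25	0.25
0.25	0.25	0.25	0.25
0.045	0.455	0.045	0.455
0.045	0.455	0.045	0.455
0.03	0.91	0.03	0.03
0.03	0.91	0.03	0.03
>AP1
0.03	0.03	0.03	0.91
0.03	0.03	0.91	0.03
0.91	0.03	0.03	0.03
0.045	0.455	0.455	0.045
0.03	0.03	0.03	0.91
0.03	0.91	0.03	0.03
0.91	0.03	0.03	0.03
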