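theta_deg,fp,replicate
0,0.29,1
0,0.29,2
0,0.29,3
0,0.30,4
0,0.30,5
45,1.23,1
45,1.21,2
45,1.21,3
45,1.22,4
45,1.22,5
90,0.55,1
90,0.55,2
90,0.55,3
90,0.58,4
90,0.58,5
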