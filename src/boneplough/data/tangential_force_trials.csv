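h_mm,theta_deg,fp_n,replicate
0.5,0,64.35,1
0.5,0,80.04,2
0.5,0,60.56,3
0.5,0,71.70,4
0.5,0,75.46,5
0.6,0,88.61,1
0.6,0,95.58,2
0.6,0,92.24,3
0.6,0,96.63,4
0.6,0,78.30,5
0.8,0,126.84,1
0.8,0,146.06,2
0.8,0,142.96,3
0.8,0,141.90,4
0.8,0,171.60,5
0.5,45,314.57,1
0.5,45,277.75,2
0.5,45,266.73,3
0.5,45,296.38,4
0.5,45,255.31,5
0.6,45,374.95,1
0.6,45,383.11,2
0.6,45,393.60,3
0.6,45,349.87,4
0.6,45,395.99,5
0.8,45,528.01,1
0.8,45,528.79,2
0.8,45,542.52,3
0.8,45,534.53,4
0.8,45,525.84,5
0.5,90,145.83,1
0.5,90,136.02,2
0.5,90,164.39,3
0.5,90,155.29,4
0.5,90,128.36,5
0.6,90,172.33,1
0.6,90,194.27,2
0.6,90,188.69,3
0.6,90,190.56,4
0.6,90,160.52,5
0.8,90,282.28,1
0.8,90,299.33,2
0.8,90,266.69,3
0.8,90,244.23,4
0.8,90,312.95,5
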