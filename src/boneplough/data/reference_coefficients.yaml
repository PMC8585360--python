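C: 707.53
alpha: 0.39
fp0: 0.29
C1: 0.294
C2: 0.934
C3: 0.45
theta0_deg: 0.0
convention: canonical
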