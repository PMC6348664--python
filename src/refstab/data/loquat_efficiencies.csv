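gene,efficiency_pct,r_squared
RPL4,102.91,0.994
RPL18,106.49,0.999
HIS3,92.83,0.999
TUA3,108.74,0.999
SAMDC,99.05,0.999
TIP41,126.43,0.996
UGPase,93.33,0.996
18S,118.84,0.999
GAPDH,104.97,0.998
PIP2,94.92,0.997
ACT,105.39,0.999
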