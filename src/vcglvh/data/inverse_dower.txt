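# Inverse Dower matrix: 12-lead to orthogonal X/Y/Z.
# Rows: X, Y, Z.  Columns (in order): I  II  V1  V2  V3  V4  V5  V6
 0.156  -0.010  -0.172  -0.074   0.122   0.231   0.239   0.194
-0.227   0.887   0.057  -0.019  -0.106  -0.022   0.041   0.048
 0.022   0.102  -0.229  -0.310  -0.246  -0.063   0.055   0.108
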