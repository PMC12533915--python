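# P-window least-squares transform (PLSV), synthetic stand-in.
# Derived in-package: least-squares regression of known orthogonal XYZ loops
# on their Dower-forward-projected 8-lead signals, P-window samples only
# (scripts/derive_lsv_matrices.py).  Editable; replace with a transcription of a
# published PLSV matrix if one is available.
# Rows: X, Y, Z.  Columns (in order): I  II  V1  V2  V3  V4  V5  V6
 0.1115   0.0220  -0.0947   0.0039   0.1491   0.2017   0.1880   0.1442
-0.1413   0.6340   0.1079   0.1041   0.0510   0.0543   0.0516   0.0203
 0.0014  -0.0157  -0.0792  -0.1212  -0.1074  -0.0520  -0.0067   0.0206
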