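# QRS-window least-squares transform (QLSV), synthetic stand-in.
# Derived in-package: least-squares regression of known orthogonal XYZ loops
# on their Dower-forward-projected 8-lead signals, QRS-window samples only
# (scripts/derive_lsv_matrices.py).  Editable; replace with a transcription of a
# published QLSV matrix if one is available.
# Rows: X, Y, Z.  Columns (in order): I  II  V1  V2  V3  V4  V5  V6
 0.1480  -0.0100  -0.1698  -0.0824   0.1271   0.2305   0.2486   0.1836
-0.2398   0.8758   0.0514  -0.0192  -0.1020  -0.0145   0.0336   0.0580
 0.0174   0.0994  -0.2227  -0.3145  -0.2470  -0.0595   0.0571   0.1093
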