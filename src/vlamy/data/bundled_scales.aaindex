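H HNC
D Normalized consensus hydrophobicity scale (Eisenberg et al. 1984),
  transcribed from the published table
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.25   -1.76   -0.64   -0.72    0.04   -0.69   -0.62    0.16   -0.40    0.73
    0.53   -1.10    0.26    0.61   -0.07   -0.26   -0.18    0.37    0.02    0.54
//
H CHAM830107
D A parameter of charge transfer capability (Charton-Charton 1983):
  indicator of the residues bearing a charge-transfer accepting group
  (-COOH or -CONH2), i.e. D, E, N, Q; transcribed offline, not a verbatim
  AAIndex dump
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      0.      0.      1.      1.      0.      1.      1.      0.      0.      0.
      0.      0.      0.      0.      0.      0.      0.      0.      0.      0.
//
H BULH740101
D Transfer free energy to surface, kcal/mol (Bull-Breese 1974),
  transcribed from the published table
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.610   0.690   0.890   0.610   0.360   0.970   0.510   0.810   0.690  -1.450
  -1.650   0.460  -0.660  -1.520  -0.170   0.420   0.290  -1.200  -1.430  -0.750
//
H CHOP780202
D Beta-sheet conformational parameter P_beta (Chou-Fasman 1978),
  transcribed from the published table
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.83    0.93    0.89    0.54    1.19    1.10    0.37    0.75    0.87    1.60
    1.30    0.74    1.05    1.38    0.55    0.75    1.19    1.37    1.47    1.70
//
H TOPIDP
D TOP-IDP intrinsic disorder propensity (Campen et al. 2008),
  transcribed from the published table
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.060   0.180   0.007   0.192   0.020   0.318   0.736   0.166   0.303  -0.486
  -0.326   0.586  -0.397  -0.697   0.987   0.341   0.059  -0.884  -0.510  -0.121
//
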