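H KLEP840101
D Net charge (Klein et al., 1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.      1.      0.     -1.      0.      0.     -1.      0.      0.      0.
     0.      1.      0.      0.      0.      0.      0.      0.      0.      0.
//
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H SYNHYD0001
D Synthetic hydrophobicity-like scale (constructed stand-in, not a published index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.5    -4.0    -3.2    -3.6     2.2    -3.1    -3.3    -0.2    -2.9     4.1
     3.5    -3.7     1.6     2.5    -1.4    -0.6    -0.5    -0.7    -1.1     3.9
//
H SYNCHG0001
D Synthetic charge-like scale (constructed stand-in, not a published index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.9     0.0    -0.9     0.0     0.0    -0.8     0.0     0.3     0.0
     0.0     1.1     0.0     0.0     0.0     0.1     0.0     0.0     0.0     0.0
//
H SYNSIZ0001
D Synthetic residue-volume-like scale (constructed stand-in, not a published index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.31    0.70    0.46    0.44    0.36    0.55    0.54    0.20    0.61    0.59
     0.59    0.67    0.61    0.70    0.41    0.33    0.43    0.85    0.73    0.51
//
H SYNNAX0001
D Synthetic incomplete scale with a missing value (constructed stand-in)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.5     0.1     0.2     0.3     NA      0.4     0.2     0.1     0.6     0.7
     0.8     0.2     0.5     0.9     0.3     0.2     0.3     1.0     0.6     0.7
//
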