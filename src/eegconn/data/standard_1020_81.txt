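# Extended 10-20 (10-10) scalp montage, 81 electrodes.
# Columns: label x y z (unitless scene coordinates, nose +y).
# Coordinates from the standard template head used by common EEG software.
Fp1 -2.944 8.392 -0.699
Fpz 0.011 8.825 -0.171
Fp2 2.987 8.49 -0.708
AF7 -5.484 6.857 -1.059
AF5 -4.543 7.286 0.598
AF3 -3.37 7.684 2.123
AF1 -1.847 7.99 3.275
AFz 0.023 8.077 3.542
AF2 1.982 8.03 3.276
AF4 3.571 7.773 2.196
AF6 4.658 7.381 0.603
AF8 5.574 6.966 -1.076
F9 -7.01 4.165 -4.995
F7 -7.026 4.247 -1.142
F5 -6.447 4.804 1.692
F3 -5.024 5.311 4.219
F1 -2.75 5.693 6.034
Fz 0.031 5.851 6.646
F2 2.951 5.76 5.954
F4 5.184 5.43 4.081
F6 6.791 4.983 1.637
F8 7.304 4.442 -1.2
F10 7.211 4.207 -5.045
FT9 -8.408 1.457 -5.043
FT7 -8.078 1.412 -1.114
FT8 8.182 1.542 -1.133
FT10 8.411 1.436 -5.054
FC5 -7.721 1.864 2.446
FC3 -6.018 2.272 5.554
FC1 -3.406 2.601 7.999
FCz 0.038 2.739 8.867
FC2 3.478 2.644 7.881
FC4 6.229 2.372 5.563
FC6 7.953 1.994 2.444
T9 -8.589 -1.583 -4.828
T7 -8.416 -1.602 -0.935
T8 8.508 -1.502 -0.949
T10 8.556 -1.636 -4.827
C5 -8.028 -1.376 2.916
C3 -6.536 -1.163 6.436
C1 -3.616 -0.998 8.975
Cz 0.04 -0.917 10.024
C2 3.767 -0.962 8.841
C4 6.712 -1.09 6.358
C6 8.346 -1.278 2.921
TP9 -8.562 -4.651 -4.571
TP7 -8.483 -4.602 -0.706
TP8 8.555 -4.555 -0.713
TP10 8.616 -4.704 -4.587
CP5 -7.959 -4.655 3.095
CP3 -6.356 -4.701 6.562
CP1 -3.551 -4.729 9.131
CPz 0.039 -4.732 9.943
CP2 3.838 -4.707 9.07
CP4 6.661 -4.664 6.558
CP6 8.332 -4.61 3.121
P9 -7.301 -7.377 -4.1
P7 -7.243 -7.345 -0.249
P5 -6.727 -7.629 2.838
P3 -5.301 -7.879 5.594
P1 -2.862 -8.052 7.544
Pz 0.032 -8.111 8.262
P2 3.192 -8.049 7.672
P4 5.567 -7.856 5.656
P6 6.789 -7.59 2.809
P8 7.306 -7.307 -0.254
P10 7.389 -7.439 -4.122
PO7 -5.484 -9.753 0.279
PO5 -4.842 -9.934 2.16
PO3 -3.651 -10.085 3.717
PO1 -1.897 -10.177 4.654
POz 0.022 -10.218 5.061
PO2 1.988 -10.179 4.639
PO4 3.678 -10.085 3.64
PO6 4.982 -9.945 2.173
PO8 5.567 -9.763 0.273
O1 -2.941 -11.245 0.884
Oz 0.011 -11.489 1.466
O2 2.984 -11.216 0.88
Nz 0.147 8.507 -3.484
Iz 0 -11.856 -2.308
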