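subject,n_frames,n_detected,det_acc_pct,auto_chews,manual_chews,chew_acc_pct,auto_bites,manual_bites,bite_acc_pct
Sub01,15014,14972,99.7,1500,1595,94.04,52,60,86.67
Sub02,15084,14972,99.3,1500,1594,94.10,52,56,92.86
Sub03,11474,11378,99.2,1056,1049,99.33,44,39,87.18
Sub04,14361,14291,99.5,1205,1153,95.49,67,60,88.33
Sub05,17770,17727,99.8,1324,1199,89.57,63,57,89.47
Sub06,15414,15369,99.7,1647,1313,74.56,70,65,92.31
Sub07,17972,17853,99.3,2040,1979,96.92,92,87,94.25
Sub08,18426,18341,99.5,2120,2056,96.89,108,106,98.11
Sub09,5810,5760,99.1,648,687,94.32,23,22,95.45
Sub10,9294,9229,99.3,777,713,91.02,49,53,92.45
Sub11,13449,13359,99.3,1059,926,85.64,54,52,96.15
Sub12,7497,7482,99.8,572,538,93.68,35,31,87.10
Sub13,10028,9877,98.5,1003,935,92.73,54,52,96.15
Sub14,12472,12429,99.7,1545,1523,98.56,65,61,93.44
Sub15,10098,10009,99.1,1174,1220,96.23,52,52,100.00
Sub16,14380,14318,99.6,1781,1733,97.23,91,94,96.81
Sub17,179531,178526,99.4,20273,19844,97.84,932,940,99.15
Sub18,11523,11469,99.5,1517,1678,90.41,75,84,89.29
Sub19,15206,15097,99.3,2024,2126,95.20,108,121,89.26
Sub20,12663,12623,99.7,1932,1907,98.69,83,82,98.78
Sub21,30222,30105,99.6,2654,2317,85.46,113,100,87.00
Sub22,11548,11524,99.8,1616,1467,89.84,62,60,96.67
Sub23,19403,19329,99.6,1974,1748,87.07,94,81,83.95
Sub24,23578,23405,99.3,2033,2020,99.36,103,100,97.00
Sub25,8447,8404,99.5,839,895,93.74,45,50,90.00
Sub26,12682,12575,99.2,1713,1786,95.91,66,69,95.65
Sub27,12071,11978,99.2,1316,1385,95.02,59,58,98.28
Sub28,9670,9563,98.9,883,949,93.05,48,63,76.19
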