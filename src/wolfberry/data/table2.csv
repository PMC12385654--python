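x1,x2,x3,hardness,ssc,ta,vc
0.66,0.51,0.18,14.08,6.25,1.76,22.23
0.68,0.62,0.49,12.56,10.36,2.34,15.34
0.27,0.13,0.15,19.76,9.12,4.12,17.36
0.91,0.85,0.36,13.30,8.45,2.19,16.28
0.77,0.03,0.23,22.15,16.59,0.82,18.25
0.31,0.28,0.97,11.13,20.16,0.98,22.16
0.63,0.69,0.82,9.67,19.26,0.71,17.52
0.50,1.00,0.85,9.84,6.15,0.75,12.35
0.20,0.92,0.77,14.28,14.61,0.49,26.42
0.79,0.77,0.05,18.33,12.34,0.95,14.65
0.29,0.97,0.31,20.94,5.36,1.03,21.35
0.70,0.95,0.59,15.06,10.57,1.26,18.46
0.95,0.64,0.64,12.12,14.46,1.09,14.52
0.22,0.08,0.74,18.59,15.26,0.42,16.79
0.11,0.44,0.26,24.21,5.43,3.43,9.36
0.75,0.36,0.69,14.31,11.52,1.12,12.52
0.13,0.41,0.72,22.03,16.85,0.36,19.56
0.47,0.77,0.00,16.26,14.36,2.42,11.54
0.84,0.33,0.38,15.53,13.42,1.34,17.56
0.24,0.23,0.46,18.40,12.46,0.97,17.42
0.79,0.10,0.90,14.02,21.35,1.52,21.52
0.98,0.56,0.21,11.30,17.42,1.03,13.26
0.43,0.82,0.56,17.60,19.54,1.52,16.52
0.38,0.59,0.33,18.00,11.26,1.95,14.26
0.15,0.72,0.51,19.46,15.62,2.75,21.36
0.40,0.49,0.67,17.31,18.43,0.46,18.42
0.57,0.21,0.10,15.65,17.26,0.95,8.79
0.61,0.38,1.00,12.60,21.03,0.25,28.42
0.59,0.87,0.28,9.63,19.42,2.15,7.69
0.52,0.15,0.77,11.14,17.03,1.26,18.79
0.86,0.90,0.87,8.01,18.06,0.85,21.52
0.73,0.05,0.54,12.27,20.71,3.41,12.89
0.54,0.31,0.44,16.25,12.36,0.95,19.52
1.00,0.18,0.62,11.14,21.59,1.09,18.42
0.45,0.00,0.41,16.53,15.62,0.56,15.49
0.34,0.67,0.92,17.57,13.52,0.26,11.03
0.93,0.26,0.08,14.11,11.34,1.96,16.85
0.36,0.46,0.03,20.25,21.52,2.63,18.42
0.89,0.54,0.95,8.97,19.53,1.65,12.85
0.18,0.74,0.13,19.61,15.85,2.09,18.04
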