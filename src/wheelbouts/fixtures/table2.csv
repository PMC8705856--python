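# Published reference bout durations (seconds) from the first validation
# experiment series of the original wheelchair mobility study: ten bouts per
# trial over four trials, measured by a human timer (recorded), the phone
# pipeline, and the watch pipeline.
trial,bout,recorded,phone,watch
3,1,15.33,14.97,14.00
3,2,16.30,15.57,14.15
3,3,13.07,10.80,10.77
3,4,17.65,18.35,16.30
3,5,16.23,15.69,14.07
3,6,10.50,10.87,9.64
3,7,19.88,19.17,18.23
3,8,15.13,12.91,14.00
3,9,16.31,16.30,15.74
3,10,17.35,15.69,15.95
4,1,17.32,17.77,18.41
4,2,16.88,15.68,15.69
4,3,17.76,15.63,14.36
4,4,15.85,14.26,14.58
4,5,18.61,16.99,17.11
4,6,17.57,15.56,15.93
4,7,20.33,18.35,19.56
4,8,23.58,21.07,22.08
4,9,20.43,19.63,19.32
4,10,19.93,19.78,19.02
5,1,19.55,18.49,18.60
5,2,15.32,14.20,13.97
5,3,18.63,16.93,17.05
5,4,19.86,18.28,17.53
5,5,19.92,19.71,19.23
5,6,16.52,20.98,20.84
5,7,19.49,17.74,16.93
5,8,18.73,18.29,18.85
5,9,18.00,18.29,18.09
5,10,24.56,21.68,20.02
6,1,12.70,13.52,13.90
6,2,20.15,20.31,19.01
6,3,18.95,18.96,18.34
6,4,19.83,19.66,17.97
6,5,18.83,17.73,16.96
6,6,19.90,18.95,18.66
6,7,14.03,12.98,14.06
6,8,17.40,16.37,15.41
6,9,20.26,19.16,18.53
6,10,14.41,13.72,13.01
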