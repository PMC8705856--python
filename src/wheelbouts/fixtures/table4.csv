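# Published reference bout durations (seconds) from the second validation
# experiment series of the original wheelchair mobility study: sixteen bouts
# (two per trial, eight trials) measured by a wheel-mounted GT3X reference
# accelerometer and by six phones on a tray.
bout,gt3x,nexus6,pixel1,pixel2,pixel3,samsung,zte
Bout1_1,52.33,52.00,50.69,51.16,51.28,50.61,49.88
Bout1_2,64.08,61.65,52.25,57.48,58.39,57.39,57.93
Bout1_3,57.68,56.44,52.25,52.61,52.28,50.25,52.44
Bout1_4,63.98,61.58,59.80,60.18,62.72,64.06,61.95
Bout1_5,39.40,37.66,37.63,38.51,37.97,37.95,33.75
Bout1_6,48.19,46.63,39.17,39.46,43.80,43.85,45.57
Bout1_7,42.15,40.18,37.21,37.19,38.08,38.81,38.62
Bout1_8,39.57,39.32,36.79,37.77,36.11,38.66,36.84
Bout2_1,61.40,59.96,59.79,58.72,58.88,61.04,60.30
Bout2_2,70.92,70.37,69.66,66.27,69.00,67.82,66.81
Bout2_3,63.28,61.53,58.60,58.70,59.60,58.45,58.40
Bout2_4,68.66,68.16,65.73,66.86,63.97,59.82,65.14
Bout2_5,42.00,41.37,40.78,40.69,42.56,40.82,41.59
Bout2_6,49.42,50.07,45.89,44.75,47.49,47.11,45.30
Bout2_7,46.59,46.46,45.94,47.08,47.11,63.42,51.15
Bout2_8,47.26,48.68,45.89,44.17,46.67,43.42,46.47
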