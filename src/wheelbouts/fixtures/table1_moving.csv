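# Published reference example of value differentiation along one axis
# (unit: m/s^2) from the original wheelchair mobility validation study:
# ten consecutive raw readings during movement and the nine printed
# consecutive-sample differences.  The final row has no printed difference
# partner, so its diff cell is empty.
raw,diff_printed
3.432328,-0.49033
2.941995,0.39499
3.336985,0.231546
3.568531,0.463092
4.031623,0.177064
4.208687,-0.40861
3.800077,-0.27241
3.52767,-1.19859
2.329079,2.955616
5.284695,
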