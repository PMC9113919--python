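id,components,mean_speed,span,orientation
a,2 1 5,24.000,2.00,157.52
b,3 1 6,24.000,4.83,67.50
c,4 1 7,24.000,6.27,27.86
d,8 1 12,24.000,4.00,157.49
e,9 1 13,24.000,7.31,75.36
f,11 1 15,24.000,10.07,23.48
g,1 5,20.108,1.00,157.52
h,2 1,29.761,1.00,157.52
i,10 1 14,24.000,7.84,45.00
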