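id,v0,sf0,tf0,distance,angle
c1,24.000,0.500,12.000,0.00,0.0
c2,35.522,0.379,13.459,1.00,157.5
c3,35.522,0.660,23.438,2.41,67.5
c4,16.215,1.149,18.626,3.13,27.9
c5,16.215,0.660,10.699,1.00,-22.5
c6,16.215,0.379,6.144,2.41,-112.5
c7,35.522,0.218,7.730,3.14,-152.1
c8,52.576,0.287,15.100,2.00,157.5
c9,52.576,0.660,34.690,3.66,75.4
c10,24.000,1.149,27.569,3.92,45.0
c11,10.956,2.000,21.911,5.04,23.5
c12,10.956,0.871,9.538,2.00,-22.5
c13,10.956,0.379,4.151,3.66,-104.6
c14,24.000,0.218,5.222,3.92,-135.0
c15,52.576,0.125,6.572,5.04,-156.5
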