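code,n,mean,sd
M0:1:6,480,1.5048,1.9379
M0:1:8,480,1.1751,1.6337
M0:2:6,480,1.6752,2.1613
M0:2:8,480,1.4624,1.9085
Ma:1:6,480,1.4761,1.9251
Ma:1:8,480,1.1640,1.6403
Ma:2:6,480,1.6050,2.1241
Ma:2:8,480,1.4691,1.9329
Mab:1:6,480,1.4691,1.9329
Mab:1:8,480,0.9911,1.2941
Mab:2:6,480,0.9911,1.2941
Mab:2:8,480,0.9911,1.2941
Mabc:1:6,480,1.4387,1.7699
Mabc:1:8,480,0.9193,1.2585
Mabc:2:6,480,1.6905,1.9796
Mabc:2:8,480,1.3890,1.6188
Mabd:1:6,480,1.4637,1.7734
Mabd:1:8,480,0.9590,1.2747
Mabd:2:6,480,1.7066,1.9868
Mabd:2:8,480,1.4050,1.6266
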