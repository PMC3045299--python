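# Frozen reference generator configuration.
# Boundary constants fixed once by kernelcc.synthetic_data.calibrate against
# the raw-data calibration targets Az(x2)=0.772, Az(x1)=0.490, R=0.25
# (dense grid, 4 pools of 200k subjects, seed 20260924; achieved
# Az(x1)=0.495, Az(x2)=0.779, R=0.259).
a0: 4.5
c0: 1.6
m0: 0.25
m: 200
pool_size: 20000
x1_low: 0.0
x1_high: 1.0
z1_mean: 5.0
z1_sd: 1.0
seed: 0
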