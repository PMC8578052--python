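source,lung,blood,liver,bone,spleen,intestine,kidneys,bladder,others
lung,0.717,0.022,0.023,0.122,0.000,0.000,0.000,0.000,0.115
blood,0.039,0.818,0.013,0.043,0.000,0.000,0.000,0.000,0.086
liver,0.007,0.002,0.872,0.022,0.000,0.013,0.002,0.000,0.071
bone,0.019,0.004,0.012,0.682,0.001,0.004,0.000,0.000,0.248
spleen,0.000,0.000,0.002,0.044,0.650,0.000,0.044,0.000,0.252
intestine,0.000,0.000,0.008,0.004,0.000,0.898,0.007,0.000,0.067
kidneys,0.000,0.000,0.009,0.002,0.005,0.046,0.806,0.000,0.129
bladder,0.000,0.000,0.000,0.005,0.000,0.001,0.000,0.742,0.249
others,0.005,0.002,0.011,0.074,0.001,0.018,0.005,0.002,0.785
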