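0.213
0.275
0.099
0.388
0.497
0.087
0.073
0.089
0.061
0.086
0.089
0.790
0.118
0.075
0.297
0.119
0.299
0.315
0.403
0.192
0.308
0.191
0.909
0.168
0.135
0.314
0.117
0.120
0.183
0.714
0.143
0.374
0.859
0.084
0.089
0.215
0.297
0.992
0.330
0.817
0.298
0.258
0.123
0.815
0.088
0.102
0.203
0.199
0.185
0.257
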