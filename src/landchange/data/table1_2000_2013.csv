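class,FL,IFL,CL,O,CoL,W,row_total,loss
FL,20.80,0.01,0.13,0.02,0.20,0.03,21.23,0.39
IFL,17.71,12.59,0.36,0.07,0.71,0.01,31.46,18.84
CL,1.58,0.42,23.25,8.95,0.85,0.01,35.06,11.74
O,0.00,0.00,0.02,9.05,0.43,0.00,9.51,0.47
CoL,0.00,0.00,0.01,0.00,2.41,0.00,2.41,0.03
W,0.04,0.01,0.00,0.00,0.00,0.29,0.34,0.05
col_total,40.17,13.02,23.77,18.10,4.61,0.34,,
gain,19.34,0.43,0.51,9.04,2.21,0.05,,
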