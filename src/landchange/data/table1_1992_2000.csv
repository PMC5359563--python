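class,FL,IFL,CL,O,CoL,W,row_total,loss
FL,17.85,0.06,0.01,0.00,0.01,0.00,17.93,0.08
IFL,3.11,30.06,0.37,0.01,0.09,0.01,33.66,3.60
CL,0.23,1.29,34.62,6.08,0.16,0.00,42.39,7.77
O,0.00,0.00,0.01,3.38,0.30,0.00,3.69,0.31
CoL,0.00,0.03,0.03,0.03,1.84,0.00,1.94,0.10
W,0.03,0.01,0.01,0.00,0.00,0.33,0.38,0.06
col_total,21.23,31.46,35.06,9.51,2.41,0.34,,
gain,3.38,1.39,0.44,6.13,0.56,0.01,,
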