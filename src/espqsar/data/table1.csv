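id,activity,inv_vs_max,inv_vs_min,lumo,vs_mean,vs_plus_mean,predicted_activity
1,1.070,0.036231884058,-0.028793550245,-0.12697,1.770,9.71,0.916
2,0.244,0.050994390617,-0.030284675954,-0.11702,1.930,7.34,0.178
3,0.486,0.025419420437,-0.032164683178,-0.12618,2.070,9.45,0.475
4,0.148,0.031220730565,-0.027502750275,-0.10432,1.150,8.62,0.134
5,0.118,0.027233115468,-0.029744199881,-0.11628,1.980,7.43,0.070
6,0.286,0.038925652005,-0.026198585276,-0.09969,0.740,9.39,0.284
7,0.097,0.042589437819,-0.028546959749,-0.11178,1.080,7.60,0.239
8,0.313,0.023110700254,-0.036630036630,-0.13221,3.080,10.93,0.379
9,0.081,0.010163634516,-0.029655990510,-0.11040,1.640,8.88,0.023
10,0.107,0.010383137784,-0.028612303290,-0.12205,1.300,5.35,0.071
11,0.026,0.019364833462,-0.041666666667,-0.14175,5.890,12.10,0.069
12,0.114,0.020512820513,-0.034141345169,-0.12015,4.600,11.66,0.049
13,0.649,0.027685492802,-0.028288543140,-0.12480,1.650,9.05,0.758
14,0.229,0.010041168792,-0.021213406873,-0.10284,2.730,8.64,0.275
15,0.242,0.030571690614,-0.027056277056,-0.11469,1.310,7.02,0.285
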