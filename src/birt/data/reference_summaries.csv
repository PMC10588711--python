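source_table,dataset,model,block,name,mean,sd,hdi_3%,hdi_97%
table2,BONE,1PL,pystan,theta[0],2.201,0.501,1.257,3.133
table2,BONE,1PL,pystan,theta[1],3.387,0.61,2.25,4.531
table2,BONE,1PL,pystan,theta[2],3.105,0.583,2.055,4.233
table2,BONE,1PL,pystan,theta[3],2.845,0.556,1.8,3.882
table2,BONE,1PL,pystan,theta[4],1.383,0.452,0.511,2.205
table2,BONE,1PL,pystan,theta[5],2.401,0.517,1.443,3.378
table2,BONE,1PL,pystan,theta[6],2.2,0.5,1.273,3.153
table2,BONE,1PL,numpyro_cpu,theta[0],2.2,0.508,1.277,3.185
table2,BONE,1PL,numpyro_cpu,theta[1],3.391,0.615,2.26,4.567
table2,BONE,1PL,numpyro_cpu,theta[2],3.099,0.586,2.0,4.201
table2,BONE,1PL,numpyro_cpu,theta[3],2.845,0.553,1.818,3.888
table2,BONE,1PL,numpyro_cpu,theta[4],1.382,0.454,0.517,2.225
table2,BONE,1PL,numpyro_cpu,theta[5],2.4,0.519,1.449,3.392
table2,BONE,1PL,numpyro_cpu,theta[6],2.198,0.506,1.267,3.174
table2,BONE,1PL,numpyro_gpu,theta[0],2.199,0.506,1.242,3.134
table2,BONE,1PL,numpyro_gpu,theta[1],3.384,0.615,2.252,4.556
table2,BONE,1PL,numpyro_gpu,theta[2],3.1,0.585,2.015,4.212
table2,BONE,1PL,numpyro_gpu,theta[3],2.843,0.556,1.786,3.875
table2,BONE,1PL,numpyro_gpu,theta[4],1.379,0.451,0.538,2.236
table2,BONE,1PL,numpyro_gpu,theta[5],2.4,0.521,1.466,3.419
table2,BONE,1PL,numpyro_gpu,theta[6],2.199,0.506,1.262,3.163
table3,BONE,2PL,pystan,theta[0],2.062,0.49,1.128,2.976
table3,BONE,2PL,pystan,theta[1],3.086,0.605,1.966,4.231
table3,BONE,2PL,pystan,theta[2],2.677,0.539,1.664,3.687
table3,BONE,2PL,pystan,theta[3],2.585,0.571,1.534,3.658
table3,BONE,2PL,pystan,theta[4],1.252,0.412,0.482,2.029
table3,BONE,2PL,pystan,theta[5],2.096,0.536,1.102,3.111
table3,BONE,2PL,pystan,theta[6],2.169,0.511,1.206,3.125
table3,BONE,2PL,numpyro_cpu,theta[0],2.057,0.486,1.159,2.991
table3,BONE,2PL,numpyro_cpu,theta[1],3.086,0.607,1.943,4.196
table3,BONE,2PL,numpyro_cpu,theta[2],2.676,0.546,1.679,3.723
table3,BONE,2PL,numpyro_cpu,theta[3],2.581,0.576,1.515,3.674
table3,BONE,2PL,numpyro_cpu,theta[4],1.248,0.409,0.494,2.037
table3,BONE,2PL,numpyro_cpu,theta[5],2.095,0.533,1.106,3.094
table3,BONE,2PL,numpyro_cpu,theta[6],2.167,0.511,1.194,3.104
table3,BONE,2PL,numpyro_gpu,theta[0],2.063,0.487,1.159,2.988
table3,BONE,2PL,numpyro_gpu,theta[1],3.09,0.601,1.975,4.226
table3,BONE,2PL,numpyro_gpu,theta[2],2.68,0.546,1.658,3.701
table3,BONE,2PL,numpyro_gpu,theta[3],2.585,0.576,1.525,3.682
table3,BONE,2PL,numpyro_gpu,theta[4],1.251,0.411,0.503,2.046
table3,BONE,2PL,numpyro_gpu,theta[5],2.096,0.538,1.105,3.112
table3,BONE,2PL,numpyro_gpu,theta[6],2.171,0.513,1.237,3.162
table4,BRAIN,1PL,pystan,theta[0],1.615,0.567,0.569,2.695
table4,BRAIN,1PL,pystan,theta[1],0.929,0.53,-0.044,1.946
table4,BRAIN,1PL,pystan,theta[2],1.617,0.57,0.561,2.698
table4,BRAIN,1PL,pystan,theta[3],0.926,0.527,-0.075,1.902
table4,BRAIN,1PL,pystan,theta[4],1.139,0.537,0.145,2.163
table4,BRAIN,1PL,pystan,theta[5],1.144,0.543,0.117,2.147
table4,BRAIN,1PL,pystan,theta[6],-0.641,0.476,-1.557,0.23
table4,BRAIN,1PL,pystan,theta[7],-1.251,0.474,-2.144,-0.362
table4,BRAIN,1PL,pystan,theta[8],1.615,0.566,0.548,2.677
table4,BRAIN,1PL,pystan,theta[9],0.721,0.515,-0.234,1.702
table4,BRAIN,1PL,pystan,theta[10],1.615,0.566,0.568,2.693
table4,BRAIN,1PL,pystan,theta[11],1.615,0.567,0.568,2.695
table4,BRAIN,1PL,pystan,theta[12],0.166,0.492,-0.766,1.078
table4,BRAIN,1PL,pystan,theta[13],0.346,0.499,-0.607,1.264
table4,BRAIN,1PL,numpyro_cpu,theta[0],1.615,0.562,0.613,2.722
table4,BRAIN,1PL,numpyro_cpu,theta[1],0.921,0.527,-0.056,1.924
table4,BRAIN,1PL,numpyro_cpu,theta[2],1.612,0.565,0.545,2.667
table4,BRAIN,1PL,numpyro_cpu,theta[3],0.921,0.527,-0.062,1.922
table4,BRAIN,1PL,numpyro_cpu,theta[4],1.141,0.539,0.122,2.139
table4,BRAIN,1PL,numpyro_cpu,theta[5],1.136,0.538,0.129,2.153
table4,BRAIN,1PL,numpyro_cpu,theta[6],-0.643,0.473,-1.51,0.256
table4,BRAIN,1PL,numpyro_cpu,theta[7],-1.253,0.474,-2.141,-0.36
table4,BRAIN,1PL,numpyro_cpu,theta[8],1.614,0.567,0.555,2.678
table4,BRAIN,1PL,numpyro_cpu,theta[9],0.718,0.515,-0.253,1.69
table4,BRAIN,1PL,numpyro_cpu,theta[10],1.611,0.566,0.519,2.648
table4,BRAIN,1PL,numpyro_cpu,theta[11],1.612,0.568,0.556,2.701
table4,BRAIN,1PL,numpyro_cpu,theta[12],0.163,0.491,-0.752,1.093
table4,BRAIN,1PL,numpyro_cpu,theta[13],0.339,0.499,-0.584,1.294
table4,BRAIN,1PL,numpyro_gpu,theta[0],1.618,0.561,0.581,2.689
table4,BRAIN,1PL,numpyro_gpu,theta[1],0.925,0.527,-0.06,1.914
table4,BRAIN,1PL,numpyro_gpu,theta[2],1.615,0.568,0.564,2.697
table4,BRAIN,1PL,numpyro_gpu,theta[3],0.923,0.527,-0.057,1.929
table4,BRAIN,1PL,numpyro_gpu,theta[4],1.143,0.537,0.151,2.166
table4,BRAIN,1PL,numpyro_gpu,theta[5],1.139,0.541,0.157,2.196
table4,BRAIN,1PL,numpyro_gpu,theta[6],-0.641,0.474,-1.524,0.247
table4,BRAIN,1PL,numpyro_gpu,theta[7],-1.252,0.476,-2.139,-0.354
table4,BRAIN,1PL,numpyro_gpu,theta[8],1.617,0.567,0.551,2.672
table4,BRAIN,1PL,numpyro_gpu,theta[9],0.722,0.515,-0.275,1.67
table4,BRAIN,1PL,numpyro_gpu,theta[10],1.613,0.566,0.559,2.689
table4,BRAIN,1PL,numpyro_gpu,theta[11],1.614,0.566,0.546,2.681
table4,BRAIN,1PL,numpyro_gpu,theta[12],0.166,0.492,-0.754,1.097
table4,BRAIN,1PL,numpyro_gpu,theta[13],0.342,0.498,-0.576,1.307
table5,BRAIN,2PL,pystan,theta[0],1.18,0.531,0.203,2.181
table5,BRAIN,2PL,pystan,theta[1],0.902,0.496,-0.008,1.843
table5,BRAIN,2PL,pystan,theta[2],1.254,0.518,0.296,2.235
table5,BRAIN,2PL,pystan,theta[3],0.704,0.538,-0.3,1.707
table5,BRAIN,2PL,pystan,theta[4],1.136,0.503,0.226,2.111
table5,BRAIN,2PL,pystan,theta[5],1.04,0.52,0.096,2.035
table5,BRAIN,2PL,pystan,theta[6],-0.509,0.394,-1.235,0.242
table5,BRAIN,2PL,pystan,theta[7],-1.27,0.433,-2.075,-0.446
table5,BRAIN,2PL,pystan,theta[8],1.458,0.572,0.369,2.512
table5,BRAIN,2PL,pystan,theta[9],0.94,0.531,-0.024,1.965
table5,BRAIN,2PL,pystan,theta[10],1.767,0.575,0.696,2.852
table5,BRAIN,2PL,pystan,theta[11],1.365,0.509,0.411,2.317
table5,BRAIN,2PL,pystan,theta[12],0.332,0.453,-0.51,1.193
table5,BRAIN,2PL,pystan,theta[13],0.324,0.465,-0.542,1.209
table5,BRAIN,2PL,numpyro_cpu,theta[0],1.183,0.528,0.182,2.157
table5,BRAIN,2PL,numpyro_cpu,theta[1],0.898,0.488,0.009,1.837
table5,BRAIN,2PL,numpyro_cpu,theta[2],1.256,0.515,0.288,2.225
table5,BRAIN,2PL,numpyro_cpu,theta[3],0.704,0.535,-0.291,1.711
table5,BRAIN,2PL,numpyro_cpu,theta[4],1.134,0.501,0.19,2.071
table5,BRAIN,2PL,numpyro_cpu,theta[5],1.044,0.518,0.089,2.031
table5,BRAIN,2PL,numpyro_cpu,theta[6],-0.505,0.394,-1.225,0.262
table5,BRAIN,2PL,numpyro_cpu,theta[7],-1.265,0.432,-2.078,-0.465
table5,BRAIN,2PL,numpyro_cpu,theta[8],1.455,0.567,0.419,2.539
table5,BRAIN,2PL,numpyro_cpu,theta[9],0.943,0.53,-0.035,1.942
table5,BRAIN,2PL,numpyro_cpu,theta[10],1.766,0.573,0.644,2.801
table5,BRAIN,2PL,numpyro_cpu,theta[11],1.365,0.506,0.426,2.326
table5,BRAIN,2PL,numpyro_cpu,theta[12],0.334,0.453,-0.51,1.197
table5,BRAIN,2PL,numpyro_cpu,theta[13],0.327,0.462,-0.523,1.204
table5,BRAIN,2PL,numpyro_gpu,theta[0],1.186,0.527,0.226,2.197
table5,BRAIN,2PL,numpyro_gpu,theta[1],0.897,0.488,0.001,1.827
table5,BRAIN,2PL,numpyro_gpu,theta[2],1.251,0.517,0.292,2.22
table5,BRAIN,2PL,numpyro_gpu,theta[3],0.702,0.532,-0.303,1.695
table5,BRAIN,2PL,numpyro_gpu,theta[4],1.133,0.5,0.204,2.08
table5,BRAIN,2PL,numpyro_gpu,theta[5],1.04,0.515,0.081,2.007
table5,BRAIN,2PL,numpyro_gpu,theta[6],-0.507,0.392,-1.248,0.228
table5,BRAIN,2PL,numpyro_gpu,theta[7],-1.264,0.433,-2.076,-0.458
table5,BRAIN,2PL,numpyro_gpu,theta[8],1.455,0.565,0.395,2.504
table5,BRAIN,2PL,numpyro_gpu,theta[9],0.942,0.528,-0.051,1.925
table5,BRAIN,2PL,numpyro_gpu,theta[10],1.762,0.573,0.644,2.807
table5,BRAIN,2PL,numpyro_gpu,theta[11],1.363,0.504,0.414,2.302
table5,BRAIN,2PL,numpyro_gpu,theta[12],0.33,0.449,-0.503,1.18
table5,BRAIN,2PL,numpyro_gpu,theta[13],0.33,0.463,-0.529,1.203
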