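province,region,index,lisa_class,local_moran,p_value,neighbor_mean
Beijing,east,0.693,HH,0.234,0.012,0.671
Tianjin,east,0.681,HH,0.198,0.067,0.652
Hebei,east,0.562,LH,0.145,0.134,0.687
Liaoning,east,0.587,HL,-0.123,0.156,0.512
Shanghai,east,0.758,HH,0.312,0.003,0.698
Jiangsu,east,0.742,HH,0.287,0.001,0.712
Zhejiang,east,0.718,HH,0.265,0.018,0.689
Fujian,east,0.687,HH,0.223,0.025,0.671
Shandong,east,0.645,HH,0.201,0.031,0.634
Guangdong,east,0.725,HH,0.298,0.002,0.634
Hainan,east,0.634,HL,-0.098,0.201,0.592
Shanxi,central,0.498,LL,0.167,0.078,0.523
Jilin,central,0.523,LL,0.134,0.178,0.534
Heilongjiang,central,0.489,LL,0.156,0.092,0.506
Anhui,central,0.634,HH,0.176,0.084,0.668
Jiangxi,central,0.578,LH,0.142,0.145,0.641
Henan,central,0.591,LH,0.138,0.162,0.617
Hubei,central,0.612,LH,0.151,0.128,0.648
Hunan,central,0.598,LH,0.133,0.169,0.625
Inner Mongolia,west,0.445,LL,0.189,0.089,0.467
Guangxi,west,0.556,LL,0.145,0.137,0.589
Chongqing,west,0.623,HL,-0.087,0.223,0.576
Sichuan,west,0.534,LL,0.172,0.095,0.558
Guizhou,west,0.421,LL,0.198,0.047,0.456
Yunnan,west,0.478,LL,0.163,0.099,0.501
Tibet,west,0.387,LL,0.234,0.038,0.412
Shaanxi,west,0.467,LL,0.181,0.087,0.493
Gansu,west,0.398,LL,0.212,0.042,0.431
Qinghai,west,0.376,LL,0.198,0.049,0.408
Ningxia,west,0.412,LL,0.167,0.091,0.445
Xinjiang,west,0.423,LL,0.189,0.083,0.434
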