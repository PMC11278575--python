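# Blank-subtracted calibration responses (uA): delta = endpoint current minus
# the same sensor's blank current, as printed (two decimals).
sensor_id,concentration_uM,delta_uA
1,10,6.41
1,50,6.69
1,100,6.78
1,200,6.74
1,400,6.51
1,600,7.10
1,800,6.37
1,1000,5.86
1,1200,4.89
1,1400,0.00
1,1600,0.00
2,10,6.37
2,50,6.53
2,100,6.45
2,200,6.37
2,400,6.31
2,600,6.19
2,800,5.55
2,1000,4.51
2,1200,2.83
2,1400,1.27
2,1600,-0.02
3,10,6.76
3,50,6.98
3,100,7.23
3,200,7.15
3,400,7.27
3,600,7.27
3,800,6.35
3,1000,5.59
3,1200,4.07
3,1400,2.33
3,1600,3.56
4,10,6.12
4,50,6.67
4,100,6.72
4,200,6.71
4,400,6.43
4,600,6.51
4,800,6.18
4,1000,5.53
4,1200,4.75
4,1400,3.66
4,1600,3.26
5,10,7.45
5,50,7.02
5,100,7.00
5,200,6.92
5,400,6.67
5,600,6.53
5,800,6.24
5,1000,4.97
5,1200,4.18
5,1400,3.07
5,1600,2.29
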