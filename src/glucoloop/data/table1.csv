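# Chronoamperometric endpoint currents (uA) for five screen-printed sweat-glucose
# biosensors across the blank + 11-concentration glucose panel.
# concentration_uM=0 with is_blank=1 encodes the blank control.
# Two cells deviate from the printed source and carry provenance flags in the
# loader: sensor 3 / 50 uM stored as -3.00 (sign-corrected for arithmetic
# consistency with the blank-subtracted table), and the duplicated "100 uM"
# column header read as 1000 uM.
sensor_id,concentration_uM,is_blank,current_uA
1,0,1,-9.98
1,10,0,-3.57
1,50,0,-3.29
1,100,0,-3.20
1,200,0,-3.24
1,400,0,-3.47
1,600,0,-2.88
1,800,0,-3.61
1,1000,0,-4.12
1,1200,0,-5.09
1,1400,0,-9.98
1,1600,0,-9.98
2,0,1,-9.39
2,10,0,-3.02
2,50,0,-2.86
2,100,0,-2.94
2,200,0,-3.02
2,400,0,-3.08
2,600,0,-3.20
2,800,0,-3.84
2,1000,0,-4.88
2,1200,0,-6.56
2,1400,0,-8.12
2,1600,0,-9.41
3,0,1,-9.98
3,10,0,-3.22
3,50,0,-3.00
3,100,0,-2.75
3,200,0,-2.83
3,400,0,-2.71
3,600,0,-2.71
3,800,0,-3.63
3,1000,0,-4.39
3,1200,0,-5.91
3,1400,0,-7.65
3,1600,0,-6.42
4,0,1,-9.98
4,10,0,-3.86
4,50,0,-3.31
4,100,0,-3.26
4,200,0,-3.27
4,400,0,-3.55
4,600,0,-3.47
4,800,0,-3.80
4,1000,0,-4.45
4,1200,0,-5.23
4,1400,0,-6.32
4,1600,0,-6.72
5,0,1,-9.98
5,10,0,-2.53
5,50,0,-2.96
5,100,0,-2.98
5,200,0,-3.06
5,400,0,-3.31
5,600,0,-3.45
5,800,0,-3.74
5,1000,0,-5.01
5,1200,0,-5.80
5,1400,0,-6.91
5,1600,0,-7.69
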