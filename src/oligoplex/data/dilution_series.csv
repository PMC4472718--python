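kit,channel,amount_ng,ct_mean,ct_sd
rotor_gene,orange,1,9.32,0.36
rotor_gene,orange,0.1,12.52,0.29
rotor_gene,orange,0.01,15.70,0.30
rotor_gene,orange,0.001,19.17,0.13
rotor_gene,orange,0.0001,22.42,0.12
rotor_gene,orange,0.00001,25.84,0.21
rotor_gene,orange,0.000001,29.09,0.10
rotor_gene,yellow,1,9.68,0.36
rotor_gene,yellow,0.1,12.84,0.28
rotor_gene,yellow,0.01,16.00,0.34
rotor_gene,yellow,0.001,19.39,0.12
rotor_gene,yellow,0.0001,22.65,0.13
rotor_gene,yellow,0.00001,26.09,0.17
rotor_gene,yellow,0.000001,29.36,0.08
rotor_gene,red,1,11.71,0.37
rotor_gene,red,0.1,14.92,0.39
rotor_gene,red,0.01,18.19,0.31
rotor_gene,red,0.001,21.74,0.17
rotor_gene,red,0.0001,24.98,0.17
rotor_gene,red,0.00001,28.48,0.17
rotor_gene,red,0.000001,31.83,0.08
rotor_gene,crimson,1,9.76,0.32
rotor_gene,crimson,0.1,12.97,0.35
rotor_gene,crimson,0.01,16.21,0.35
rotor_gene,crimson,0.001,19.75,0.19
rotor_gene,crimson,0.0001,23.07,0.14
rotor_gene,crimson,0.00001,26.59,0.20
rotor_gene,crimson,0.000001,29.87,0.02
rotor_gene,green,1,12.66,0.43
rotor_gene,green,0.1,15.73,0.37
rotor_gene,green,0.01,18.91,0.50
rotor_gene,green,0.001,22.55,0.13
rotor_gene,green,0.0001,25.73,0.16
rotor_gene,green,0.00001,29.23,0.20
rotor_gene,green,0.000001,32.62,0.11
ssofast,orange,1,9.13,0.36
ssofast,orange,0.1,12.11,0.11
ssofast,orange,0.01,16.28,0.16
ssofast,orange,0.001,20.89,0.56
ssofast,orange,0.0001,24.74,0.11
ssofast,orange,0.00001,28.34,0.40
ssofast,orange,0.000001,31.48,0.38
ssofast,yellow,1,8.56,0.43
ssofast,yellow,0.1,11.63,0.18
ssofast,yellow,0.01,15.70,0.11
ssofast,yellow,0.001,21.12,0.71
ssofast,yellow,0.0001,25.59,0.17
ssofast,yellow,0.00001,29.80,0.59
ssofast,yellow,0.000001,33.43,0.36
ssofast,red,1,11.93,0.29
ssofast,red,0.1,14.78,0.17
ssofast,red,0.01,19.28,0.19
ssofast,red,0.001,23.30,0.76
ssofast,red,0.0001,27.26,0.15
ssofast,red,0.00001,31.03,0.48
ssofast,red,0.000001,34.25,0.69
ssofast,crimson,1,10.41,0.31
ssofast,crimson,0.1,13.33,0.15
ssofast,crimson,0.01,17.55,0.03
ssofast,crimson,0.001,21.97,0.53
ssofast,crimson,0.0001,25.90,0.07
ssofast,crimson,0.00001,29.57,0.50
ssofast,crimson,0.000001,32.78,0.47
ssofast,green,1,14.20,0.41
ssofast,green,0.1,17.46,0.11
ssofast,green,0.01,21.58,0.11
ssofast,green,0.001,25.86,0.60
ssofast,green,0.0001,29.68,0.15
ssofast,green,0.00001,33.47,0.50
ssofast,green,0.000001,36.85,0.51
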