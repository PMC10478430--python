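pair_id,miRNA20a,miRNA21,miRNA29a,miRNA31,miRNA92,miRNA224
P1,0.03585778,0.380851302,1.06875214,0.016550802,1.376933695,0.348727511
P2,1.09645,0.744853227,0.634025639,0.28162107,43.60894807,19.04037414
P3,1.692489273,0.19090725,0.29605899,0.066645422,16.1857784,0.117350079
P4,1.827198884,0.415489365,0.385843106,0.125200289,0.089000864,0.038028682
P5,0.165149779,0.405168741,1.017076664,0.339575209,0.423256334,0.035356511
P6,9.032603896,1.486654886,2.40478338,0.446682873,1.377598043,0.346092903
P7,0.086177313,5.109981798,2.836372188,0.223606276,0.545315661,0.025755563
P8,0.036665352,0.595136416,0.609622383,0.672004739,15.27884066,0.050267673
P9,0.791830378,0.433974719,7.749368098,1.218222488,39.81362463,2.231345879
P10,1.394741901,0.453943997,0.435070972,0.40896525,0.073191164,0.06857601
P11,1.114735233,1.975651409,1.682212004,42.32879328,153.2597858,0.831435329
P12,14.54973359,3.999988297,32.62794428,0.375873656,18.4565922,1.431082595
P13,14.40626287,0.631038396,1.104248944,0.291989528,18.90293824,1.304937537
P14,0.928942468,1.719170222,1.31107852,6.881585216,1.284949901,0.353125807
P15,20.67402285,1.515992607,1.799639358,1.184994819,1.523399321,0.250151106
P16,1.228038849,0.905169764,3.674614842,0.411291757,34.59836117,0.896321213
P17,26.635528,0.026303388,0.052693645,0.041371318,0.138602656,0.035727369
P18,0.67089814,2.075354337,18.2393941,5.40911457,17.46464893,1.408999347
P19,0.114868611,11.72405865,212.6193329,0.330265922,4589.949761,15.08672611
P20,11.96089471,1.273562362,10.3128689,0.562961827,25.40671426,1.975487901
P22,10.67585162,3.782676577,20.47102061,0.034650289,87.78290945,3.899262033
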