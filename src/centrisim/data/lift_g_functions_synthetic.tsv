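# Synthetic Ho-Leal-type surrogate for the lift wall-distance weighting
# functions G1(s) (wall-induced, boundary-layer decay 0.08) and G2(s)
# (shear-gradient, ~[s(1-s)]^3).  Constructed, not digitized from any
# reference; calibrated so the square-channel (AR=1) equilibria sit at
# s = 0.2/0.8 and stay off the walls (s* in ~0.12-0.2) across the
# tabulated AR range.  columns: s  G1  G2   (version 2)
1.000000e-02 8.824927e-01 1.088321e-05
2.000000e-02 7.787960e-01 8.445392e-05
3.000000e-02 6.872839e-01 2.763952e-04
4.000000e-02 6.065245e-01 6.351046e-04
5.000000e-02 5.352545e-01 1.202077e-03
6.000000e-02 4.723587e-01 2.012282e-03
7.000000e-02 4.168531e-01 3.094529e-03
8.000000e-02 3.678693e-01 4.471828e-03
9.000000e-02 3.246410e-01 6.161739e-03
1.000000e-01 2.864918e-01 8.176720e-03
1.100000e-01 2.528249e-01 1.052446e-02
1.200000e-01 2.231135e-01 1.320819e-02
1.300000e-01 1.968927e-01 1.622704e-02
1.400000e-01 1.737525e-01 1.957632e-02
1.500000e-01 1.533307e-01 2.324782e-02
1.600000e-01 1.353077e-01 2.723011e-02
1.700000e-01 1.194018e-01 3.150886e-02
1.800000e-01 1.053639e-01 3.606705e-02
1.900000e-01 9.297442e-02 4.088533e-02
2.000000e-01 8.203960e-02 4.594218e-02
2.100000e-01 7.238831e-02 5.121424e-02
2.200000e-01 6.386957e-02 5.667656e-02
2.300000e-01 5.635008e-02 6.230276e-02
2.400000e-01 4.971222e-02 6.806535e-02
2.500000e-01 4.385212e-02 7.393591e-02
2.600000e-01 3.867810e-02 7.988529e-02
2.700000e-01 3.410921e-02 8.588384e-02
2.800000e-01 3.007397e-02 9.190162e-02
2.900000e-01 2.650926e-02 9.790856e-02
3.000000e-01 2.335928e-02 1.038746e-01
3.100000e-01 2.057478e-02 1.097701e-01
3.200000e-01 1.811217e-02 1.155655e-01
3.300000e-01 1.593293e-02 1.212322e-01
3.400000e-01 1.400298e-02 1.267419e-01
3.500000e-01 1.229210e-02 1.320675e-01
3.600000e-01 1.077353e-02 1.371826e-01
3.700000e-01 9.423526e-03 1.420622e-01
3.800000e-01 8.220953e-03 1.466822e-01
3.900000e-01 7.146999e-03 1.510202e-01
4.000000e-01 6.184863e-03 1.550548e-01
4.100000e-01 5.319491e-03 1.587666e-01
4.200000e-01 4.537344e-03 1.621375e-01
4.300000e-01 3.826186e-03 1.651511e-01
4.400000e-01 3.174889e-03 1.677930e-01
4.500000e-01 2.573265e-03 1.700502e-01
4.600000e-01 2.011901e-03 1.719121e-01
4.700000e-01 1.482014e-03 1.733695e-01
4.800000e-01 9.753130e-04 1.744156e-01
4.900000e-01 4.838713e-04 1.750453e-01
5.000000e-01 0.000000e+00 1.752555e-01
5.100000e-01 -4.838713e-04 1.750453e-01
5.200000e-01 -9.753130e-04 1.744156e-01
5.300000e-01 -1.482014e-03 1.733695e-01
5.400000e-01 -2.011901e-03 1.719121e-01
5.500000e-01 -2.573265e-03 1.700502e-01
5.600000e-01 -3.174889e-03 1.677930e-01
5.700000e-01 -3.826186e-03 1.651511e-01
5.800000e-01 -4.537344e-03 1.621375e-01
5.900000e-01 -5.319491e-03 1.587666e-01
6.000000e-01 -6.184863e-03 1.550548e-01
6.100000e-01 -7.146999e-03 1.510202e-01
6.200000e-01 -8.220953e-03 1.466822e-01
6.300000e-01 -9.423526e-03 1.420622e-01
6.400000e-01 -1.077353e-02 1.371826e-01
6.500000e-01 -1.229210e-02 1.320675e-01
6.600000e-01 -1.400298e-02 1.267419e-01
6.700000e-01 -1.593293e-02 1.212322e-01
6.800000e-01 -1.811217e-02 1.155655e-01
6.900000e-01 -2.057478e-02 1.097701e-01
7.000000e-01 -2.335928e-02 1.038746e-01
7.100000e-01 -2.650926e-02 9.790856e-02
7.200000e-01 -3.007397e-02 9.190162e-02
7.300000e-01 -3.410921e-02 8.588384e-02
7.400000e-01 -3.867810e-02 7.988529e-02
7.500000e-01 -4.385212e-02 7.393591e-02
7.600000e-01 -4.971222e-02 6.806535e-02
7.700000e-01 -5.635008e-02 6.230276e-02
7.800000e-01 -6.386957e-02 5.667656e-02
7.900000e-01 -7.238831e-02 5.121424e-02
8.000000e-01 -8.203960e-02 4.594218e-02
8.100000e-01 -9.297442e-02 4.088533e-02
8.200000e-01 -1.053639e-01 3.606705e-02
8.300000e-01 -1.194018e-01 3.150886e-02
8.400000e-01 -1.353077e-01 2.723011e-02
8.500000e-01 -1.533307e-01 2.324782e-02
8.600000e-01 -1.737525e-01 1.957632e-02
8.700000e-01 -1.968927e-01 1.622704e-02
8.800000e-01 -2.231135e-01 1.320819e-02
8.900000e-01 -2.528249e-01 1.052446e-02
9.000000e-01 -2.864918e-01 8.176720e-03
9.100000e-01 -3.246410e-01 6.161739e-03
9.200000e-01 -3.678693e-01 4.471828e-03
9.300000e-01 -4.168531e-01 3.094529e-03
9.400000e-01 -4.723587e-01 2.012282e-03
9.500000e-01 -5.352545e-01 1.202077e-03
9.600000e-01 -6.065245e-01 6.351046e-04
9.700000e-01 -6.872839e-01 2.763952e-04
9.800000e-01 -7.787960e-01 8.445392e-05
9.900000e-01 -8.824927e-01 1.088321e-05
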