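# Inertial-lift correction coefficients versus channel aspect
# ratio AR = W/H (DNS-derived values as printed).
# columns: AR  C1  C2   (version 1)
1.000 0.056 0.030
2.000 0.021 0.018
4.000 0.023 0.127
6.000 0.068 0.135
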