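age,q_annual
44,0.002
45,0.0021435469250725863
46,0.00229739670999407
47,0.002462288826689833
48,0.0026390158215457886
49,0.00282842712474619
50,0.0030314331330207962
51,0.0032490095854249418
52,0.0034822022531844966
53,0.0037321319661472296
54,0.004
55,0.004287093850145173
56,0.0045947934199881395
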