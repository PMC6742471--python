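dog_age,q_annual
2,0.024488888020923416
3,0.024488888020923416
4,0.024488888020923416
5,0.024488888020923416
6,0.024488888020923416
7,0.024488888020923416
8,0.024488888020923416
9,0.024488888020923416
10,0.024488888020923416
11,0.024488888020923416
12,0.024488888020923416
13,0.024488888020923416
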