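stratum,quarter,n_entering,n_alive,n_dead,n_ltfu
<16.0,1,5096,3649,881,566
<16.0,2,3649,3131,181,337
<16.0,3,3131,2875,73,183
<16.0,4,2875,2689,40,146
16.00-16.99,1,4439,3608,468,363
16.00-16.99,2,3608,3222,124,262
16.00-16.99,3,3222,2995,45,182
16.00-16.99,4,2995,2813,34,148
17.00-18.49,1,9712,8421,631,660
17.00-18.49,2,8421,7630,228,563
17.00-18.49,3,7630,7177,103,350
17.00-18.49,4,7177,6849,58,270
>18.5,1,39133,35716,1229,2188
>18.5,2,35716,33417,460,1839
>18.5,3,33417,31850,251,1316
>18.5,4,31850,30432,200,1218
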