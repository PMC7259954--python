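motor,duty_ratio,adp_release_rate_per_s,condition_group
MYH13,0.1,400,johnson_skeletal
MYH7,0.1,59,johnson_skeletal
MYH10,0.3,0.37,nonmuscle
MYO1B,0.05,2.1,nonmuscle
MYO5A,0.7,12,high_duty
MYO6,0.9,5.6,high_duty
MYO7A,0.9,2.1,high_duty
MYO10,0.6,18,high_duty
"MYH11, wild-type",0.15,79,sweeney_gizzard
"MYH11, alanine sub.",0.15,34,sweeney_gizzard
"MYH11, Xenopus",0.15,40,sweeney_gizzard
"MYH11, dloop 1",0.15,13,sweeney_gizzard
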