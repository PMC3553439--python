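# Normalized fetal growth curve: fraction of 40-week (term) weight by
# gestational week. Monotone, 0 at conception, 1 at 40 weeks. Synthetic
# reference curve with the shape of standard fetal-weight references;
# scaled per individual so the value at the dyad's gestational age equals
# the observed birth weight. Overridable by the user.
gestational_week,fraction_of_term_weight
0,0.0
8,0.0003
12,0.006
16,0.03
20,0.086
24,0.19
28,0.31
32,0.51
36,0.74
38,0.87
40,1.0
42,1.09
44,1.15
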