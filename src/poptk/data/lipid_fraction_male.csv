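# Body lipid mass fraction (kg lipid / kg body weight) by age, males.
# Synthetic reference curve assembled for this package from the shape of
# published infant/adult body-composition references; values at age 0 match
# the model's fetal lipid fraction (15% male). Overridable by the user.
age_years,fraction
0.0,0.15
0.25,0.22
0.5,0.25
1.0,0.23
2.0,0.20
3.0,0.18
4.0,0.17
5.0,0.16
10.0,0.18
15.0,0.16
18.0,0.17
25.0,0.19
35.0,0.21
45.0,0.23
60.0,0.25
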