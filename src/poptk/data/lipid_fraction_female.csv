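# Body lipid mass fraction (kg lipid / kg body weight) by age, females.
# Synthetic reference curve assembled for this package from the shape of
# published infant/adult body-composition references; values at age 0 match
# the model's fetal lipid fraction (14% female). Overridable by the user.
age_years,fraction
0.0,0.14
0.25,0.22
0.5,0.25
1.0,0.24
2.0,0.21
3.0,0.20
4.0,0.19
5.0,0.19
10.0,0.21
15.0,0.25
18.0,0.28
25.0,0.29
35.0,0.31
45.0,0.33
60.0,0.34
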