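strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
B,total_FAs,temperature_C,pH 5,normal saturated,15:0,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,normal saturated,15:0,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,normal saturated,16:0,fa,5,11.80,0.99,10,13.18,3.99,15,12.13,0.98,20,11.31,1.59,25,12.09,1.44,0.010,0.73
B,total_FAs,pH,25C,normal saturated,16:0,fa,5,12.09,1.44,6,13.94,4.77,7,12.69,1.02,8,17.08,1.84,,,,0.27,0.081
B,total_FAs,temperature_C,pH 5,normal saturated,18:0,fa,5,4.94,1.54,10,5.90,3.17,15,3.42,0.41,20,6.19,3.21,25,2.39,0.62,0.23,0.28
B,total_FAs,pH,25C,normal saturated,18:0,fa,5,2.39,0.62,6,1.87,0.87,7,2.40,0.64,8,3.62,0.67,,,,0.30,0.067
B,total_FAs,temperature_C,pH 5,normal saturated,Total normal saturated,group_total,5,16.74,2.53,10,19.07,5.50,15,15.56,1.39,20,17.50,4.80,25,14.48,2.06,0.83,0.35
B,total_FAs,pH,25C,normal saturated,Total normal saturated,group_total,5,14.48,2.06,6,15.82,3.91,7,15.08,1.35,8,20.70,2.28,,,,0.38,0.032
B,total_FAs,temperature_C,pH 5,branched saturated,iso 14:0,fa,5,n.d.,,10,2.80,2.52,15,n.d.,,20,n.d.,,25,0.13,0.22,,
B,total_FAs,pH,25C,branched saturated,iso 14:0,fa,5,0.13,0.22,6,0.31,0.53,7,0.22,0.38,8,n.d.,,,,,0.26,0.092
B,total_FAs,temperature_C,pH 5,branched saturated,iso 15:0,fa,5,5.61,0.37,10,7.09,1.08,15,6.03,0.32,20,7.27,0.61,25,10.10,1.00,0.59,7.83E-04
B,total_FAs,pH,25C,branched saturated,iso 15:0,fa,5,10.10,1.00,6,6.35,0.99,7,6.50,1.22,8,9.23,2.24,,,,0.02,0.68
B,total_FAs,temperature_C,pH 5,branched saturated,anteiso 15:0,fa,5,2.52,0.22,10,1.72,1.54,15,1.49,0.16,20,0.25,0.44,25,0.23,0.40,0.81,4.84E-06
B,total_FAs,pH,25C,branched saturated,anteiso 15:0,fa,5,0.23,0.40,6,n.d.,,7,0.14,0.24,8,n.d.,,,,,,1.30E-02
B,total_FAs,temperature_C,pH 5,branched saturated,iso 16:0,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,branched saturated,iso 16:0,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,branched saturated,Total branched saturated,group_total,5,8.13,0.59,10,11.60,1.37,15,7.52,0.20,20,7.53,0.73,25,10.45,1.62,0.002,0.88
B,total_FAs,pH,25C,branched saturated,Total branched saturated,group_total,5,10.45,1.62,6,6.65,0.48,7,6.85,0.91,8,9.23,2.24,,,,0.04,0.55
B,total_FAs,temperature_C,pH 5,normal unsaturated,15:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,normal unsaturated,15:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,normal unsaturated,16:1,fa,5,33.69,1.43,10,33.71,1.87,15,32.65,2.33,20,33.11,2.59,25,30.86,1.29,0.21,0.083
B,total_FAs,pH,25C,normal unsaturated,16:1,fa,5,30.86,1.29,6,33.05,1.30,7,31.54,2.03,8,7.70,0.78,,,,0.57,4.68E-03
B,total_FAs,temperature_C,pH 5,normal unsaturated,17:1,fa,5,7.89,1.70,10,4.49,1.41,15,2.33,0.28,20,n.d.,,25,0.57,0.52,0.77,1.85E-05
B,total_FAs,pH,25C,normal unsaturated,17:1,fa,5,0.57,0.52,6,0.46,0.09,7,0.71,0.05,8,n.d.,,,,,0.05,0.49
B,total_FAs,temperature_C,pH 5,normal unsaturated,18:1,fa,5,0.36,0.34,10,n.d.,,15,n.d.,,20,n.d.,,25,0.32,0.29,0.09,0.29
B,total_FAs,pH,25C,normal unsaturated,18:1,fa,5,0.32,0.29,6,3.18,5.50,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,normal unsaturated,Total normal unsaturated,group_total,5,41.94,0.38,10,38.20,0.78,15,34.99,2.04,20,33.11,2.59,25,31.76,2.05,0.83,2.31E-06
B,total_FAs,pH,25C,normal unsaturated,Total normal unsaturated,group_total,5,31.76,2.05,6,36.69,6.62,7,32.25,1.99,8,7.70,0.78,,,,0.53,7.10E-03
B,total_FAs,temperature_C,pH 5,branched unsaturated,iso 15:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,branched unsaturated,iso 15:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,branched unsaturated,iso 16:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,branched unsaturated,iso 16:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,branched unsaturated,Total branched unsaturated,group_total,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_FAs,pH,25C,branched unsaturated,Total branched unsaturated,group_total,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_FAs,temperature_C,pH 5,,Total non-hydroxy FAs,grand_total,5,66.82,2.89,10,68.89,6.23,15,58.06,3.62,20,58.13,6.64,25,56.69,5.08,0.45,6.54E-03
B,total_FAs,pH,25C,,Total non-hydroxy FAs,grand_total,5,56.69,5.08,6,59.16,10.09,7,54.18,3.91,8,37.62,0.10,,,,0.51,9.20E-03
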