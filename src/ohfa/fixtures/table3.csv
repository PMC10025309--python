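strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
C,total_FAs,temperature_C,pH 5,normal saturated,15:0,fa,5,n.d.,,10,0.17,0.29,15,n.d.,,20,n.d.,,25,n.d.,,0.07,0.23
C,total_FAs,pH,25C,normal saturated,15:0,fa,5,n.d.,,6,0.35,0.30,7,0.37,0.32,8,0.48,0.42,,,,0.41,1.94E-05
C,total_FAs,temperature_C,pH 5,normal saturated,16:0,fa,5,11.82,0.78,10,9.02,1.96,15,7.06,1.29,20,8.17,0.72,25,6.69,1.12,0.56,1.32E-03
C,total_FAs,pH,25C,normal saturated,16:0,fa,5,6.69,1.12,6,8.03,1.97,7,18.15,5.54,8,9.39,2.66,,,,0.15,0.21
C,total_FAs,temperature_C,pH 5,normal saturated,18:0,fa,5,10.58,1.06,10,4.08,0.81,15,1.85,0.39,20,5.76,0.59,25,6.20,0.68,0.12,0.21
C,total_FAs,pH,25C,normal saturated,18:0,fa,5,6.20,0.68,6,1.28,0.07,7,2.74,1.13,8,1.47,1.29,,,,0.45,0.016
C,total_FAs,temperature_C,pH 5,normal saturated,Total normal saturated,group_total,5,22.40,1.58,10,13.27,2.55,15,8.91,1.67,20,13.93,1.14,25,12.89,1.68,0.31,0.031
C,total_FAs,pH,25C,normal saturated,Total normal saturated,group_total,5,12.89,1.68,6,9.31,1.94,7,21.26,5.38,8,11.34,3.69,,,,0.02,0.64
C,total_FAs,temperature_C,pH 5,branched saturated,iso 14:0,fa,5,n.d.,,10,0.57,0.52,15,0.33,0.29,20,n.d.,,25,0.66,0.11,0.07,0.33
C,total_FAs,pH,25C,branched saturated,iso 14:0,fa,5,0.66,0.11,6,0.35,0.30,7,n.d.,,8,n.d.,,,,,,
C,total_FAs,temperature_C,pH 5,branched saturated,iso 15:0,fa,5,5.13,0.24,10,4.28,3.71,15,5.29,0.93,20,7.06,3.48,25,8.96,3.64,0.26,0.053
C,total_FAs,pH,25C,branched saturated,iso 15:0,fa,5,8.96,3.64,6,8.00,2.11,7,8.99,0.54,8,11.69,1.07,,,,0.21,0.14
C,total_FAs,temperature_C,pH 5,branched saturated,anteiso 15:0,fa,5,2.20,0.23,10,3.85,3.45,15,0.82,0.73,20,n.d.,,25,0.45,0.02,0.23,0.070
C,total_FAs,pH,25C,branched saturated,anteiso 15:0,fa,5,0.45,0.02,6,n.d.,,7,0.53,0.04,8,0.63,0.04,,,,0.85,2.18E-05
C,total_FAs,temperature_C,pH 5,branched saturated,iso 16:0,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_FAs,pH,25C,branched saturated,iso 16:0,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
C,total_FAs,temperature_C,pH 5,branched saturated,Total branched saturated,group_total,5,7.33,0.29,10,8.70,0.76,15,6.44,1.02,20,7.06,3.48,25,10.06,3.56,0.06,0.40
C,total_FAs,pH,25C,branched saturated,Total branched saturated,group_total,5,10.06,3.56,6,8.35,2.23,7,9.34,0.85,8,12.33,1.12,,,,0.14,0.23
C,total_FAs,temperature_C,pH 5,normal unsaturated,15:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,0.03,0.41
C,total_FAs,pH,25C,normal unsaturated,15:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,0.22,0.38,,,,,
C,total_FAs,temperature_C,pH 5,normal unsaturated,16:1,fa,5,26.58,1.29,10,30.16,4.05,15,26.96,2.18,20,33.36,5.15,25,29.27,4.60,0.10,0.261
C,total_FAs,pH,25C,normal unsaturated,16:1,fa,5,29.27,4.60,6,32.75,3.00,7,32.22,1.98,8,38.65,4.60,,,,0.46,0.016
C,total_FAs,temperature_C,pH 5,normal unsaturated,17:1,fa,5,3.26,1.52,10,5.64,0.66,15,2.77,2.42,20,0.95,1.63,25,2.04,1.12,0.24,0.062
C,total_FAs,pH,25C,normal unsaturated,17:1,fa,5,2.04,1.12,6,2.39,0.13,7,2.95,0.32,8,4.19,0.47,,,,0.66,1.32E-03
C,total_FAs,temperature_C,pH 5,normal unsaturated,18:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,1.02,1.77,25,n.d.,,0.07,0.21
C,total_FAs,pH,25C,normal unsaturated,18:1,fa,5,n.d.,,6,n.d.,,7,0.33,0.05,8,0.64,0.16,,,,,
C,total_FAs,temperature_C,pH 5,normal unsaturated,Total normal unsaturated,group_total,5,29.84,0.29,10,35.80,3.97,15,29.73,0.68,20,35.33,7.20,25,31.31,3.52,0.007,0.77
C,total_FAs,pH,25C,normal unsaturated,Total normal unsaturated,group_total,5,31.31,3.52,6,35.14,2.90,7,35.40,2.41,8,43.49,5.12,,,,0.59,3.33E-03
C,total_FAs,temperature_C,pH 5,branched unsaturated,iso 15:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_FAs,pH,25C,branched unsaturated,iso 15:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
C,total_FAs,temperature_C,pH 5,branched unsaturated,iso 16:1,fa,5,n.d.,,10,0.21,0.37,15,n.d.,,20,n.d.,,25,n.d.,,0.07,0.25
C,total_FAs,pH,25C,branched unsaturated,iso 16:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
C,total_FAs,temperature_C,pH 5,branched unsaturated,Total branched unsaturated,group_total,5,n.d.,,10,0.21,0.37,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_FAs,pH,25C,branched unsaturated,Total branched unsaturated,group_total,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
C,total_FAs,temperature_C,pH 5,,Total non-hydroxy FAs,grand_total,5,59.58,1.46,10,57.99,5.08,15,45.08,0.48,20,56.32,7.35,25,54.27,8.56,0.06,0.36
C,total_FAs,pH,25C,,Total non-hydroxy FAs,grand_total,5,54.27,8.56,6,52.80,5.43,7,66.01,3.85,8,67.16,3.07,,,,0.52,7.74E-03
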