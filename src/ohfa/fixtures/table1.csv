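strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
A,total_FAs,temperature_C,pH 8,normal saturated,15:0,fa,5,3.08,0.16,10,4.60,0.18,15,5.59,0.42,20,7.45,0.57,25,9.15,1.10,0.94,2.11E-09
A,total_FAs,pH,25C,normal saturated,15:0,fa,5,8.41,3.27,6,12.39,0.53,7,10.34,2.34,8,9.15,1.10,,,,8.14E-05,0.98
A,total_FAs,temperature_C,pH 8,normal saturated,16:0,fa,5,8.75,5.91,10,6.25,1.29,15,6.13,0.92,20,8.43,0.74,25,12.81,2.84,0.17,0.12
A,total_FAs,pH,25C,normal saturated,16:0,fa,5,7.93,2.36,6,7.50,0.41,7,7.76,0.70,8,12.81,2.84,,,,0.38,0.032
A,total_FAs,temperature_C,pH 8,normal saturated,18:0,fa,5,2.39,0.83,10,3.71,0.46,15,1.57,0.76,20,1.27,0.49,25,2.84,0.42,0.05,0.45
A,total_FAs,pH,25C,normal saturated,18:0,fa,5,0.86,0.16,6,0.75,0.28,7,0.62,0.07,8,2.84,0.42,,,,0.48,0.013
A,total_FAs,temperature_C,pH 8,normal saturated,Total normal saturated,group_total,5,14.21,5.83,10,14.57,1.78,15,13.30,1.50,20,17.17,0.77,25,24.80,4.11,0.45,6.29E-03
A,total_FAs,pH,25C,normal saturated,Total normal saturated,group_total,5,17.21,5.44,6,20.62,0.33,7,18.73,2.95,8,24.80,4.11,,,,0.31,0.06
A,total_FAs,temperature_C,pH 8,branched saturated,iso 14:0,fa,5,0.63,0.33,10,0.47,0.03,15,0.19,0.32,20,n.d.,,25,0.68,0.02,0.05,0.42
A,total_FAs,pH,25C,branched saturated,iso 14:0,fa,5,0.77,0.26,6,0.42,0.03,7,0.47,0.05,8,0.68,0.02,,,,0.02,0.65
A,total_FAs,temperature_C,pH 8,branched saturated,iso 15:0,fa,5,18.34,0.37,10,19.27,0.81,15,22.86,3.19,20,24.18,0.55,25,22.77,1.65,0.54,1.75E-03
A,total_FAs,pH,25C,branched saturated,iso 15:0,fa,5,26.47,0.93,6,25.37,1.24,7,30.48,1.16,8,22.77,1.65,,,,0.05,0.48
A,total_FAs,temperature_C,pH 8,branched saturated,anteiso 15:0,fa,5,5.89,0.07,10,4.59,0.25,15,4.01,0.43,20,2.67,0.14,25,2.20,0.20,0.96,3.88E-10
A,total_FAs,pH,25C,branched saturated,anteiso 15:0,fa,5,1.07,0.11,6,2.06,1.72,7,1.54,0.15,8,2.20,0.20,,,,0.15,0.22
A,total_FAs,temperature_C,pH 8,branched saturated,iso 16:0,fa,5,1.07,0.31,10,1.48,0.19,15,1.19,0.21,20,0.86,0.75,25,0.98,0.03,0.06,0.37
A,total_FAs,pH,25C,branched saturated,iso 16:0,fa,5,0.09,0.16,6,n.d.,,7,n.d.,,8,0.98,0.03,,,,,
A,total_FAs,temperature_C,pH 8,branched saturated,Total branched saturated,group_total,5,25.94,0.73,10,25.82,1.22,15,28.24,3.11,20,27.71,1.08,25,26.63,1.85,0.07,0.34
A,total_FAs,pH,25C,branched saturated,Total branched saturated,group_total,5,28.40,1.19,6,27.85,1.10,7,32.50,1.27,8,26.63,1.85,,,,8.33E-04,0.93
A,total_FAs,temperature_C,pH 8,normal unsaturated,15:1,fa,5,1.41,0.19,10,1.93,0.18,15,1.92,0.11,20,1.90,0.09,25,1.86,0.25,0.25,0.057
A,total_FAs,pH,25C,normal unsaturated,15:1,fa,5,3.77,0.70,6,2.70,2.09,7,2.31,0.41,8,1.86,0.25,,,,0.35,0.045
A,total_FAs,temperature_C,pH 8,normal unsaturated,16:1,fa,5,15.61,0.35,10,15.58,0.70,15,17.85,1.34,20,17.88,1.13,25,18.08,0.63,0.58,1.05E-03
A,total_FAs,pH,25C,normal unsaturated,16:1,fa,5,16.02,2.56,6,15.49,0.80,7,18.85,0.87,8,18.08,0.63,,,,0.34,0.047
A,total_FAs,temperature_C,pH 8,normal unsaturated,17:1,fa,5,7.47,2.93,10,10.86,0.91,15,8.93,0.81,20,4.95,2.85,25,3.87,1.81,0.37,0.017
A,total_FAs,pH,25C,normal unsaturated,17:1,fa,5,4.00,2.20,6,4.27,0.87,7,3.15,0.64,8,3.87,1.81,,,,0.017,0.69
A,total_FAs,temperature_C,pH 8,normal unsaturated,18:1,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
A,total_FAs,pH,25C,normal unsaturated,18:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
A,total_FAs,temperature_C,pH 8,normal unsaturated,Total normal unsaturated,group_total,5,24.49,3.29,10,28.37,0.75,15,28.45,2.23,20,24.74,2.45,25,23.81,1.10,0.07,0.34
A,total_FAs,pH,25C,normal unsaturated,Total normal unsaturated,group_total,5,23.80,1.59,6,22.46,2.10,7,24.32,1.89,8,23.81,1.10,,,,0.019,0.67
A,total_FAs,temperature_C,pH 8,branched unsaturated,iso 15:1,fa,5,9.73,0.43,10,8.16,0.44,15,6.96,0.67,20,4.54,0.19,25,4.04,0.14,0.95,8.90E-10
A,total_FAs,pH,25C,branched unsaturated,iso 15:1,fa,5,3.41,0.38,6,3.23,0.14,7,3.39,0.23,8,4.04,0.14,,,,0.38,0.032
A,total_FAs,temperature_C,pH 8,branched unsaturated,iso 16:1,fa,5,0.22,0.38,10,0.48,0.42,15,0.24,0.41,20,n.d.,,25,n.d.,,0.56,1.27E-03
A,total_FAs,pH,25C,branched unsaturated,iso 16:1,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,0.09,0.14
A,total_FAs,temperature_C,pH 8,branched unsaturated,Total branched unsaturated,group_total,5,9.95,0.54,10,8.64,0.36,15,7.20,0.33,20,4.54,0.19,25,4.04,0.14,0.95,4.29E-10
A,total_FAs,pH,25C,branched unsaturated,Total branched unsaturated,group_total,5,3.41,0.38,6,3.23,0.14,7,3.39,0.23,8,4.04,0.14,,,,0.38,0.03
A,total_FAs,temperature_C,pH 8,,Total non-hydroxy FAs,grand_total,5,74.60,2.86,10,77.40,2.90,15,77.18,5.06,20,74.15,3.22,25,79.28,5.00,0.05,0.41
A,total_FAs,pH,25C,,Total non-hydroxy FAs,grand_total,5,72.81,5.95,6,74.16,1.55,7,78.93,5.83,8,79.28,5.00,,,,0.30,0.065
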