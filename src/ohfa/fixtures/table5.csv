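strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
B,total_3OH_FAs,temperature_C,pH 5,,iso C13,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_3OH_FAs,pH,25C,,iso C13,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_3OH_FAs,temperature_C,pH 5,,iso C14,fa,5,0.19,0.06,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_3OH_FAs,pH,25C,,iso C14,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_3OH_FAs,temperature_C,pH 5,,normal C14,fa,5,3.70,0.62,10,3.89,0.47,15,4.57,1.04,20,4.66,1.12,25,4.08,1.18,0.07,0.36
B,total_3OH_FAs,pH,25C,,normal C14,fa,5,4.08,1.18,6,16.07,17.17,7,4.53,0.51,8,5.37,0.46,,,,0.010,0.76
B,total_3OH_FAs,temperature_C,pH 5,,iso C15,fa,5,13.93,3.19,10,22.37,0.47,15,21.24,3.39,20,28.68,6.91,25,35.18,5.23,0.72,6.29E-05
B,total_3OH_FAs,pH,25C,,iso C15,fa,5,35.18,5.23,6,29.61,0.85,7,24.80,3.99,8,31.27,4.10,,,,0.08,0.35
B,total_3OH_FAs,temperature_C,pH 5,,anteiso C15,fa,5,14.61,3.09,10,15.57,1.77,15,10.24,2.26,20,6.31,1.73,25,2.55,0.64,0.82,3.12E-06
B,total_3OH_FAs,pH,25C,,anteiso C15,fa,5,2.55,0.64,6,3.56,0.85,7,3.15,0.80,8,3.43,0.25,,,,0.14,0.24
B,total_3OH_FAs,temperature_C,pH 5,,normal C15,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_3OH_FAs,pH,25C,,normal C15,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_3OH_FAs,temperature_C,pH 5,,iso C16,fa,5,2.38,0.27,10,1.40,0.30,15,0.88,0.11,20,0.37,0.14,25,0.03,0.05,0.93,9.88E-09
B,total_3OH_FAs,pH,25C,,iso C16,fa,5,0.03,0.05,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_3OH_FAs,temperature_C,pH 5,,normal C16,fa,5,20.44,1.59,10,14.45,1.26,15,18.51,1.48,20,13.87,2.03,25,9.77,0.30,0.62,4.59E-04
B,total_3OH_FAs,pH,25C,,normal C16,fa,5,9.77,0.30,6,13.11,1.98,7,13.71,0.91,8,12.34,0.95,,,,0.27,0.08
B,total_3OH_FAs,temperature_C,pH 5,,iso C17,fa,5,18.76,1.50,10,21.28,2.06,15,29.04,2.73,20,36.42,6.20,25,45.15,6.57,0.86,7.20E-07
B,total_3OH_FAs,pH,25C,,iso C17,fa,5,45.15,6.57,6,32.63,4.49,7,47.44,4.38,8,42.78,2.62,,,,0.016,0.70
B,total_3OH_FAs,temperature_C,pH 5,,anteiso C17,fa,5,25.53,3.49,10,20.25,1.95,15,14.96,2.35,20,8.71,1.39,25,2.43,0.44,0.95,5.19E-10
B,total_3OH_FAs,pH,25C,,anteiso C17,fa,5,2.43,0.44,6,4.02,0.46,7,4.99,0.49,8,3.79,0.50,,,,0.32,0.053
B,total_3OH_FAs,temperature_C,pH 5,,normal C17,fa,5,0.18,0.08,10,0.54,0.94,15,0.16,0.06,20,0.36,0.14,25,0.07,0.06,0.02,0.61
B,total_3OH_FAs,pH,25C,,normal C17,fa,5,0.07,0.06,6,n.d.,,7,n.d.,,8,n.d.,,,,,0.36,0.039
B,total_3OH_FAs,temperature_C,pH 5,,normal C18,fa,5,0.29,0.02,10,0.25,0.21,15,0.40,0.005,20,0.63,0.09,25,0.74,0.15,0.70,1.08E-03
B,total_3OH_FAs,pH,25C,,normal C18,fa,5,0.74,0.15,6,1.01,0.29,7,1.37,0.13,8,1.02,0.12,,,,0.25,0.097
B,total_3OH_FAs,temperature_C,pH 5,,Total iso 3-OH FAs,class_total,5,35.26,1.50,10,45.05,1.65,15,51.16,0.60,20,65.47,0.71,25,80.36,1.31,0.97,2.19E-11
B,total_3OH_FAs,pH,25C,,Total iso 3-OH FAs,class_total,5,80.36,1.31,6,62.23,13.74,7,72.25,1.61,8,74.05,1.70,,,,0.01,0.72
B,total_3OH_FAs,temperature_C,pH 5,,Total anteiso 3-OH FAs,class_total,5,40.13,0.41,10,35.82,1.04,15,25.20,0.09,20,15.02,0.40,25,4.97,0.52,0.98,7.88E-13
B,total_3OH_FAs,pH,25C,,Total anteiso 3-OH FAs,class_total,5,4.97,0.52,6,7.58,1.24,7,8.14,0.76,8,7.22,0.27,,,,0.36,0.04
B,total_3OH_FAs,temperature_C,pH 5,,Total normal 3-OH FAs,class_total,5,24.60,1.11,10,19.13,1.35,15,23.64,0.52,20,19.51,0.95,25,14.66,0.95,0.57,1.12E-03
B,total_3OH_FAs,pH,25C,,Total normal 3-OH FAs,class_total,5,14.66,0.95,6,30.18,14.97,7,19.61,1.07,8,18.73,1.43,,,,4.7E-04,0.95
B,total_3OH_FAs,temperature_C,pH 5,,Iso/anteiso 3-OH FAs,ratio,5,0.88,0.05,10,1.26,0.07,15,2.03,0.03,20,4.36,0.11,25,16.29,1.97,0.68,1.69E-04
B,total_3OH_FAs,pH,25C,,Iso/anteiso 3-OH FAs,ratio,5,16.29,1.97,6,8.15,0.55,7,8.94,0.06,8,10.28,0.62,,,,0.33,0.05
B,total_3OH_FAs,temperature_C,pH 5,,Iso/normal 3-OH FAs,ratio,5,1.44,0.13,10,2.37,0.25,15,2.17,0.07,20,3.36,0.20,25,5.50,0.44,0.82,3.23E-06
B,total_3OH_FAs,pH,25C,,Iso/normal 3-OH FAs,ratio,5,5.50,0.44,6,2.50,1.32,7,3.69,0.27,8,3.97,0.39,,,,0.10,0.33
B,total_3OH_FAs,temperature_C,pH 5,,Anteiso/normal 3-OH FAs,ratio,5,1.63,0.06,10,1.88,0.15,15,1.07,0.02,20,0.77,0.06,25,0.34,0.03,0.86,7.36E-07
B,total_3OH_FAs,pH,25C,,Anteiso/normal 3-OH FAs,ratio,5,0.34,0.03,6,0.30,0.15,7,0.42,0.03,8,0.39,0.01,,,,0.14,0.24
B,total_3OH_FAs,temperature_C,pH 5,,RIAN,index,5,-0.49,0.03,10,-0.63,0.04,15,-0.51,0.01,20,-0.62,0.03,25,-0.77,0.03,0.57,1.08E-03
B,total_3OH_FAs,pH,25C,,RIAN,index,5,-0.77,0.03,6,-0.39,0.30,7,-0.61,0.03,8,-0.64,0.04,,,,0.009,0.77
B,total_3OH_FAs,temperature_C,pH 5,,RAN15,index,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
B,total_3OH_FAs,pH,25C,,RAN15,index,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
B,total_3OH_FAs,temperature_C,pH 5,,RAN17,index,5,162.0,69.0,10,13.8,8.0,15,103.7,37.4,20,27.89,13.98,25,24.38,2.65,0.51,2.92E-03
B,total_3OH_FAs,pH,25C,,RAN17,index,5,24.38,2.65,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
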