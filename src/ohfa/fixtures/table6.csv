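strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
C,total_3OH_FAs,temperature_C,pH 5,,iso C13,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_3OH_FAs,pH,25C,,iso C13,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
C,total_3OH_FAs,temperature_C,pH 5,,iso C14,fa,5,0.31,0.04,10,0.34,0.14,15,0.16,0.01,20,0.10,0.09,25,0.03,0.06,0.69,1.39E-04
C,total_3OH_FAs,pH,25C,,iso C14,fa,5,0.03,0.06,6,0.12,0.06,7,0.23,0.06,8,0.27,0.04,,,,0.79,1.24E-04
C,total_3OH_FAs,temperature_C,pH 5,,normal C14,fa,5,0.79,0.17,10,1.25,0.54,15,1.32,0.33,20,2.01,0.26,25,2.48,1.40,0.50,3.37E-03
C,total_3OH_FAs,pH,25C,,normal C14,fa,5,2.48,1.40,6,3.55,1.29,7,3.11,0.64,8,3.17,0.62,,,,0.04,0.54
C,total_3OH_FAs,temperature_C,pH 5,,iso C15,fa,5,9.98,1.84,10,16.57,4.20,15,13.60,0.82,20,24.36,5.12,25,37.08,9.96,0.68,1.41E-04
C,total_3OH_FAs,pH,25C,,iso C15,fa,5,37.08,9.96,6,36.44,5.78,7,22.08,2.60,8,26.93,4.94,,,,0.37,0.036
C,total_3OH_FAs,temperature_C,pH 5,,anteiso C15,fa,5,23.04,5.28,10,26.57,5.97,15,17.95,1.64,20,14.45,3.63,25,6.45,3.19,0.67,1.73E-04
C,total_3OH_FAs,pH,25C,,anteiso C15,fa,5,6.45,3.19,6,6.33,1.00,7,4.55,0.49,8,6.16,1.26,,,,0.03,0.58
C,total_3OH_FAs,temperature_C,pH 5,,normal C15,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_3OH_FAs,pH,25C,,normal C15,fa,5,n.d.,,6,0.14,0.25,7,0.13,0.02,8,0.17,0.07,,,,0.19,0.15
C,total_3OH_FAs,temperature_C,pH 5,,iso C16,fa,5,1.78,0.23,10,1.54,0.32,15,1.28,0.13,20,1.40,0.39,25,0.91,0.05,0.55,1.47E-03
C,total_3OH_FAs,pH,25C,,iso C16,fa,5,0.91,0.05,6,1.02,0.40,7,2.29,0.18,8,1.79,0.34,,,,0.51,8.88E-03
C,total_3OH_FAs,temperature_C,pH 5,,normal C16,fa,5,1.91,0.48,10,1.54,0.49,15,2.09,0.30,20,3.77,1.64,25,5.58,1.78,0.58,9.16E-04
C,total_3OH_FAs,pH,25C,,normal C16,fa,5,5.58,1.78,6,5.03,1.13,7,8.26,0.52,8,7.54,1.41,,,,0.36,0.040
C,total_3OH_FAs,temperature_C,pH 5,,iso C17,fa,5,12.65,2.68,10,13.85,2.78,15,19.64,0.83,20,28.86,2.92,25,34.01,7.05,0.83,2.03E-06
C,total_3OH_FAs,pH,25C,,iso C17,fa,5,34.01,7.05,6,37.15,7.24,7,48.26,1.93,8,43.61,3.99,,,,0.39,0.029
C,total_3OH_FAs,temperature_C,pH 5,,anteiso C17,fa,5,48.96,3.95,10,38.19,8.68,15,43.64,1.73,20,24.11,4.32,25,10.81,5.00,0.77,1.61E-05
C,total_3OH_FAs,pH,25C,,anteiso C17,fa,5,10.81,5.00,6,9.65,1.40,7,10.21,1.93,8,9.25,1.13,,,,0.04,0.55
C,total_3OH_FAs,temperature_C,pH 5,,normal C17,fa,5,0.50,0.26,10,0.14,0.02,15,0.19,0.08,20,0.76,1.07,25,2.41,1.25,0.37,0.016
C,total_3OH_FAs,pH,25C,,normal C17,fa,5,2.41,1.25,6,0.30,0.27,7,0.48,0.26,8,0.71,0.07,,,,0.31,0.062
C,total_3OH_FAs,temperature_C,pH 5,,normal C18,fa,5,0.07,0.06,10,n.d.,,15,0.12,0.03,20,0.18,0.03,25,0.24,0.10,0.59,8.08E-04
C,total_3OH_FAs,pH,25C,,normal C18,fa,5,0.24,0.10,6,0.27,0.03,7,0.40,0.05,8,0.41,0.09,,,,0.53,7.21E-03
C,total_3OH_FAs,temperature_C,pH 5,,Total iso 3-OH FAs,class_total,5,24.71,1.84,10,32.30,2.07,15,34.69,0.80,20,54.72,3.29,25,72.03,3.52,0.90,5.75E-08
C,total_3OH_FAs,pH,25C,,Total iso 3-OH FAs,class_total,5,72.03,3.52,6,74.73,1.25,7,72.85,2.42,8,72.60,0.89,,,,7.99E-05,0.98
C,total_3OH_FAs,temperature_C,pH 5,,Total anteiso 3-OH FAs,class_total,5,72.00,2.27,10,64.76,3.05,15,61.59,1.00,20,38.56,0.71,25,17.26,7.54,0.88,1.97E-07
C,total_3OH_FAs,pH,25C,,Total anteiso 3-OH FAs,class_total,5,17.26,7.54,6,15.97,0.50,7,14.76,2.25,8,15.41,0.18,,,,0.05,0.48
C,total_3OH_FAs,temperature_C,pH 5,,Total normal 3-OH FAs,class_total,5,3.28,0.57,10,2.94,0.98,15,3.72,0.22,20,6.72,2.75,25,10.71,4.18,0.57,1.12E-03
C,total_3OH_FAs,pH,25C,,Total normal 3-OH FAs,class_total,5,10.71,4.18,6,9.30,1.75,7,12.38,0.18,8,11.99,0.93,,,,0.12,0.27
C,total_3OH_FAs,temperature_C,pH 5,,Iso/anteiso 3-OH FAs,ratio,5,0.34,0.04,10,0.50,0.06,15,0.56,0.02,20,1.42,0.11,25,5.09,3.17,0.48,4.41E-03
C,total_3OH_FAs,pH,25C,,Iso/anteiso 3-OH FAs,ratio,5,5.09,3.17,6,4.68,0.07,7,5.03,0.91,8,4.71,0.08,,,,4.23E-03,0.84
C,total_3OH_FAs,temperature_C,pH 5,,Iso/normal 3-OH FAs,ratio,5,7.63,0.97,10,11.61,2.82,15,9.33,0.37,20,9.07,3.40,25,7.26,2.08,0.04,0.49
C,total_3OH_FAs,pH,25C,,Iso/normal 3-OH FAs,ratio,5,7.26,2.08,6,8.26,1.76,7,5.89,0.28,8,6.08,0.55,,,,0.20,0.15
C,total_3OH_FAs,temperature_C,pH 5,,Anteiso/normal 3-OH FAs,ratio,5,22.46,4.64,10,23.80,7.98,15,16.59,1.20,20,6.29,2.04,25,1.92,1.18,0.78,1.33E-05
C,total_3OH_FAs,pH,25C,,Anteiso/normal 3-OH FAs,ratio,5,1.92,1.18,6,1.77,0.40,7,1.19,0.16,8,1.29,0.11,,,,0.21,0.14
C,total_3OH_FAs,temperature_C,pH 5,,RIAN,index,5,-1.47,0.08,10,-1.53,0.14,15,-1.41,0.03,20,-1.16,0.18,25,-0.94,0.18,0.67,1.74E-04
C,total_3OH_FAs,pH,25C,,RIAN,index,5,-0.94,0.18,6,-0.99,0.09,7,-0.85,0.007,8,-0.87,0.04,,,,0.16,0.19
C,total_3OH_FAs,temperature_C,pH 5,,RAN15,index,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
C,total_3OH_FAs,pH,25C,,RAN15,index,5,n.d.,,6,17.39,,7,34.49,7.10,8,40.13,11.40,,,,0.45,0.017
C,total_3OH_FAs,temperature_C,pH 5,,RAN17,index,5,126.5,86.2,10,275.4,91.9,15,258.3,127.3,20,46.6,45.6,25,6.27,5.46,0.25,0.057
C,total_3OH_FAs,pH,25C,,RAN17,index,5,6.27,5.46,6,22.98,2.18,7,23.58,7.50,8,13.10,0.33,,,,0.11,0.29
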