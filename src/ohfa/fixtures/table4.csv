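strain_id,basis,condition_variable,fixed_condition,group,label,kind,level_1,mean_1,sd_1,level_2,mean_2,sd_2,level_3,mean_3,sd_3,level_4,mean_4,sd_4,level_5,mean_5,sd_5,r2,p
A,total_3OH_FAs,temperature_C,pH 8,,iso C13,fa,5,0.15,0.006,10,0.28,0.02,15,0.33,0.06,20,0.42,0.03,25,0.48,0.03,0.91,2.59E-08
A,total_3OH_FAs,pH,25C,,iso C13,fa,5,1.15,0.36,6,0.79,0.08,7,0.54,0.21,8,0.48,0.03,,,,0.64,1.73E-03
A,total_3OH_FAs,temperature_C,pH 8,,iso C14,fa,5,0.52,0.03,10,0.45,0.04,15,0.44,0.15,20,0.37,0.04,25,0.31,0.001,0.55,1.45E-03
A,total_3OH_FAs,pH,25C,,iso C14,fa,5,n.d.,,6,0.09,0.08,7,0.21,0.07,8,0.31,0.001,,,,0.88,7.93E-06
A,total_3OH_FAs,temperature_C,pH 8,,normal C14,fa,5,2.88,0.15,10,3.06,0.45,15,3.22,0.31,20,3.69,0.08,25,6.35,0.88,0.64,3.51E-04
A,total_3OH_FAs,pH,25C,,normal C14,fa,5,7.81,2.25,6,4.66,0.52,7,5.03,1.05,8,6.35,0.88,,,,0.07,0.39
A,total_3OH_FAs,temperature_C,pH 8,,iso C15,fa,5,46.17,1.43,10,53.41,5.32,15,56.37,10.02,20,54.64,4.40,25,49.02,6.17,0.02,0.58
A,total_3OH_FAs,pH,25C,,iso C15,fa,5,65.92,7.93,6,64.32,4.78,7,59.69,9.43,8,49.02,6.17,,,,0.48,0.012
A,total_3OH_FAs,temperature_C,pH 8,,anteiso C15,fa,5,3.74,0.16,10,3.08,0.26,15,2.45,0.29,20,1.88,0.22,25,1.98,0.19,0.85,1.10E-06
A,total_3OH_FAs,pH,25C,,anteiso C15,fa,5,0.61,0.11,6,0.71,0.09,7,1.28,0.34,8,1.98,0.19,,,,0.84,2.74E-05
A,total_3OH_FAs,temperature_C,pH 8,,normal C15,fa,5,0.72,0.008,10,0.79,0.08,15,0.81,0.28,20,1.10,0.05,25,1.60,0.08,0.73,4.78E-05
A,total_3OH_FAs,pH,25C,,normal C15,fa,5,2.35,0.32,6,2.41,0.03,7,1.61,0.28,8,1.60,0.08,,,,0.64,1.79E-03
A,total_3OH_FAs,temperature_C,pH 8,,iso C16,fa,5,6.92,0.62,10,4.27,0.89,15,3.77,0.28,20,3.14,0.54,25,2.47,0.68,0.68,1.42E-04
A,total_3OH_FAs,pH,25C,,iso C16,fa,5,0.58,0.35,6,0.71,0.10,7,1.07,0.32,8,2.47,0.68,,,,0.67,1.09E-03
A,total_3OH_FAs,temperature_C,pH 8,,normal C16,fa,5,7.10,0.21,10,5.88,0.76,15,5.53,2.43,20,7.44,1.64,25,14.45,2.69,0.41,9.94E-03
A,total_3OH_FAs,pH,25C,,normal C16,fa,5,10.20,1.90,6,8.94,1.58,7,12.29,5.48,8,14.45,2.69,,,,0.28,0.078
A,total_3OH_FAs,temperature_C,pH 8,,iso C17,fa,5,26.93,0.79,10,26.30,3.79,15,25.40,3.92,20,25.95,2.23,25,21.89,3.66,0.23,0.073
A,total_3OH_FAs,pH,25C,,iso C17,fa,5,10.84,7.68,6,16.33,3.67,7,17.17,5.92,8,21.89,3.66,,,,0.41,0.026
A,total_3OH_FAs,temperature_C,pH 8,,anteiso C17,fa,5,4.81,0.30,10,2.44,0.53,15,1.62,0.86,20,1.05,0.19,25,0.75,0.23,0.79,8.29E-06
A,total_3OH_FAs,pH,25C,,anteiso C17,fa,5,0.13,0.12,6,0.32,0.05,7,0.56,0.13,8,0.75,0.23,,,,0.79,1.07E-04
A,total_3OH_FAs,temperature_C,pH 8,,normal C17,fa,5,0.07,0.06,10,0.04,0.07,15,0.07,0.12,20,0.32,0.04,25,0.70,0.05,0.71,7.94E-05
A,total_3OH_FAs,pH,25C,,normal C17,fa,5,0.42,0.37,6,0.72,0.13,7,0.54,0.07,8,0.70,0.05,,,,0.14,0.23
A,total_3OH_FAs,temperature_C,pH 8,,normal C18,fa,5,n.d.,,10,n.d.,,15,n.d.,,20,n.d.,,25,n.d.,,,
A,total_3OH_FAs,pH,25C,,normal C18,fa,5,n.d.,,6,n.d.,,7,n.d.,,8,n.d.,,,,,,
A,total_3OH_FAs,temperature_C,pH 8,,Total iso 3-OH FAs,class_total,5,80.69,0.16,10,84.71,0.74,15,86.31,4.27,20,84.52,1.75,25,74.17,1.88,0.16,0.15
A,total_3OH_FAs,pH,25C,,Total iso 3-OH FAs,class_total,5,78.49,1.03,6,82.24,1.18,7,78.69,3.85,8,74.17,1.88,,,,0.29,0.070
A,total_3OH_FAs,temperature_C,pH 8,,Total anteiso 3-OH FAs,class_total,5,8.55,0.13,10,5.52,0.29,15,4.07,1.15,20,2.93,0.35,25,2.72,0.05,0.85,1.15E-06
A,total_3OH_FAs,pH,25C,,Total anteiso 3-OH FAs,class_total,5,0.73,0.02,6,1.04,0.05,7,1.84,0.35,8,2.72,0.05,,,,0.93,5.20E-07
A,total_3OH_FAs,temperature_C,pH 8,,Total normal 3-OH FAs,class_total,5,10.77,0.13,10,9.77,0.45,15,9.62,3.13,20,12.56,1.61,25,23.10,1.86,0.54,1.81E-03
A,total_3OH_FAs,pH,25C,,Total normal 3-OH FAs,class_total,5,20.78,1.04,6,16.72,1.22,7,19.47,4.20,8,23.10,1.86,,,,0.12,0.25
A,total_3OH_FAs,temperature_C,pH 8,,Iso/anteiso 3-OH FAs,ratio,5,9.44,0.15,10,15.39,0.97,15,22.42,6.39,20,29.16,3.75,25,27.27,1.06,0.79,1.05E-05
A,total_3OH_FAs,pH,25C,,Iso/anteiso 3-OH FAs,ratio,5,107.0,2.81,6,79.48,3.30,7,43.57,7.11,8,27.27,1.06,,,,0.97,6.22E-09
A,total_3OH_FAs,temperature_C,pH 8,,Iso/normal 3-OH FAs,ratio,5,7.50,0.10,10,8.68,0.49,15,9.65,3.17,20,6.82,1.06,25,3.23,0.36,0.34,0.023
A,total_3OH_FAs,pH,25C,,Iso/normal 3-OH FAs,ratio,5,3.79,0.23,6,4.94,0.45,7,4.19,1.06,8,3.23,0.36,,,,0.11,0.28
A,total_3OH_FAs,temperature_C,pH 8,,Anteiso/normal 3-OH FAs,ratio,5,0.79,0.02,10,0.56,0.005,15,0.43,0.03,20,0.24,0.04,25,0.12,0.009,0.98,6.79E-13
A,total_3OH_FAs,pH,25C,,Anteiso/normal 3-OH FAs,ratio,5,0.04,0.02,6,0.06,0.008,7,0.10,0.04,8,0.12,0.009,,,,0.79,1.05E-04
A,total_3OH_FAs,temperature_C,pH 8,,RIAN,index,5,-0.92,0.006,10,-0.97,0.02,15,-0.99,0.15,20,-0.85,0.07,25,-0.52,0.05,0.51,2.87E-03
A,total_3OH_FAs,pH,25C,,RIAN,index,5,-0.58,0.03,6,-0.70,0.04,7,-0.62,0.12,8,-0.52,0.05,,,,0.11,0.29
A,total_3OH_FAs,temperature_C,pH 8,,RAN15,index,5,5.22,0.27,10,3.96,0.75,15,3.17,0.67,20,1.70,0.16,25,1.24,0.14,0.92,2.31E-08
A,total_3OH_FAs,pH,25C,,RAN15,index,5,0.26,0.07,6,0.30,0.04,7,0.79,0.08,8,1.24,0.14,,,,0.88,5.57E-06
A,total_3OH_FAs,temperature_C,pH 8,,RAN17,index,5,44.80,2.33,10,24.44,,15,12.51,,20,3.30,0.21,25,1.07,0.34,0.92,1.26E-08
A,total_3OH_FAs,pH,25C,,RAN17,index,5,0.31,0.03,6,0.46,0.02,7,1.02,0.10,8,1.07,0.34,,,,0.73,4.20E-04
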