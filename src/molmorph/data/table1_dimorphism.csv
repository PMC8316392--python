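subgroup,species,strain,female_N,female_A5_n,female_A5_mean,female_A5_sem,female_A5_min,female_A5_max,male_N,male_A4_n,male_A4_mean,male_A4_sem,male_A4_min,male_A4_max,male_A5_n,male_A5_mean,male_A5_sem,male_A5_min,male_A5_max,test,signif_f5_m5,p_f5_m5,signif_m4_m5,p_m4_m5,call
montium,asahinai,AM06-12,34,68,1.09,0.01,0.90,1.30,35,70,1.12,0.02,0.72,1.53,70,1.14,0.01,0.84,1.52,ANOVA,**,0.005,ns,0.62,-
montium,auraria,A662,36,72,1.06,0.01,0.93,1.27,34,68,1.10,0.01,0.94,1.50,68,1.07,0.01,0.91,1.32,ANOVA,ns,0.72,ns,0.17,-
montium,baimaii,ML11023,36,72,1.04,0.01,0.89,1.18,36,72,1.18,0.02,0.91,1.45,72,1.38,0.02,0.97,1.82,ANOVA,***,< 0.001,***,< 0.001,+
montium,biauraria,B16,35,68,1.02,0.01,0.88,1.23,33,66,1.08,0.01,0.79,1.33,66,1.08,0.01,0.89,1.41,Kruskal-Wallis,**,0.002,ns,> 0.99,-
montium,fengkainensis,XT33,33,66,1.02,0.01,0.88,1.20,36,60,1.10,0.01,0.97,1.30,60,1.08,0.01,0.78,1.25,Kruskal-Wallis,***,< 0.001,ns,> 0.99,+
montium,lacteicornis,IRUR20,41,82,0.97,0.01,0.84,1.39,37,74,1.10,0.01,0.78,1.39,74,1.38,0.02,1.03,1.86,ANOVA,***,< 0.001,***,< 0.001,+
montium,neoasahinai,OKNH2K,33,66,1.00,0.01,0.80,1.27,37,70,1.01,0.02,0.74,1.50,70,1.08,0.02,0.84,1.40,Kruskal-Wallis,**,0.004,**,0.0022,-
montium,pectinifera,OGS98m,38,76,1.06,0.01,0.84,1.25,40,80,1.13,0.01,0.92,1.59,80,1.22,0.01,0.85,1.48,ANOVA,***,< 0.001,***,< 0.001,+
montium,pseudobaimaii,ML11250,32,64,1.03,0.01,0.80,1.21,34,68,1.13,0.01,0.88,1.43,68,1.08,0.01,0.84,1.40,ANOVA,**,0.002,*,0.02,-
montium,rufa,rufa-OGM,37,74,0.98,0.01,0.82,1.26,37,72,1.00,0.01,0.81,1.27,72,1.00,0.01,0.86,1.36,ANOVA,ns,0.28,ns,0.93,-
montium,subauraria,ONM29,32,64,1.06,0.01,0.83,1.20,36,72,1.08,0.01,0.80,1.35,72,1.11,0.01,0.91,1.33,ANOVA,**,0.003,ns,0.27,-
montium,tani,MES01,36,71,1.01,0.01,0.86,1.25,41,79,1.01,0.01,0.75,1.21,78,1.05,0.01,0.85,1.46,Kruskal-Wallis,*,0.04,ns,0.11,-
montium,trapezifrons,Bavi31,40,79,0.98,0.01,0.85,1.12,39,78,1.14,0.01,0.94,1.49,78,1.10,0.01,0.91,1.46,ANOVA,***,< 0.001,*,0.04,+
montium,triauraria,T544,34,68,1.03,0.01,0.78,1.30,34,68,1.11,0.01,0.91,1.47,64,1.04,0.01,0.81,1.28,ANOVA,ns,0.95,***,< 0.001,-
kikkawai,bocki,IR2-37,36,72,1.14,0.01,0.97,1.47,37,74,1.26,0.02,0.92,1.63,74,1.41,0.02,1.05,1.92,ANOVA,***,< 0.001,***,< 0.001,+
kikkawai,kikkawai,OGH06-01,37,74,1.07,0.01,0.92,1.25,43,86,1.17,0.01,0.75,1.47,86,1.51,0.03,1.15,2.16,Kruskal-Wallis,***,< 0.001,***,< 0.001,+
kikkawai,leontia,AO-2,37,73,1.07,0.01,0.88,1.40,44,88,1.36,0.02,1.02,2.18,88,1.40,0.02,1.06,1.82,ANOVA,***,< 0.001,ns,0.15,+
kikkawai,lini,BGS3146.1,33,65,1.03,0.01,0.79,1.33,32,64,1.04,0.01,0.87,1.26,64,1.07,0.01,0.92,1.31,ANOVA,**,0.009,ns,0.05,-
kikkawai,ogumai,RGN3,39,77,1.00,0.01,0.79,1.28,37,74,1.11,0.02,0.83,1.62,73,1.23,0.02,0.86,1.52,ANOVA,***,< 0.001,***,< 0.001,+
kikkawai,ohnishii,ML45,36,72,1.05,0.01,0.81,1.32,38,76,1.09,0.01,0.81,1.43,76,1.26,0.01,0.96,1.74,ANOVA,***,< 0.001,***,< 0.001,+
punjabiensis,punjabiensis,CJB212,35,70,1.06,0.01,0.80,1.30,38,74,1.14,0.01,0.85,1.42,74,1.11,0.02,0.85,1.51,ANOVA,ns,0.07,ns,0.18,-
punjabiensis,watanabei,14028-0531.02,40,79,1.05,0.01,0.86,1.28,39,77,1.17,0.01,0.95,1.45,78,1.20,0.01,0.84,1.40,ANOVA,***,< 0.001,ns,0.27,+
orosa,orosa,14028-0611.00,33,64,1.05,0.01,0.87,1.31,34,68,1.08,0.01,0.88,1.44,68,1.10,0.02,0.91,1.67,ANOVA,*,0.01,ns,0.57,-
serrata,barbarae,ML11213,39,77,1.03,0.01,0.85,1.24,36,71,1.23,0.02,0.88,1.81,71,1.60,0.03,1.21,2.22,ANOVA,***,< 0.001,***,< 0.001,+
serrata,bicornuta,BOG1,11,22,1.09,0.02,0.98,1.35,36,72,1.09,0.01,0.87,1.44,72,1.08,0.01,0.93,1.38,ANOVA,ns,0.85,ns,0.89,-
serrata,birchii,14028-0521.00,39,77,1.02,0.01,0.87,1.33,37,74,1.11,0.01,0.83,1.47,74,1.15,0.01,0.89,1.34,Kruskal-Wallis,***,< 0.001,**,0.005,+
serrata,bunnanda,14028-0721.00,33,66,1.21,0.02,0.91,1.61,33,65,1.35,0.02,1.02,1.73,66,1.28,0.02,0.89,2.17,ANOVA,*,0.03,ns,0.08,-
serrata,cauverii,cauv-CNRS,37,74,1.14,0.01,0.89,1.40,38,76,1.15,0.01,0.96,1.38,75,1.18,0.01,0.84,1.39,ANOVA,ns,0.07,ns,0.26,-
serrata,mayri,14028-0591.00,37,73,1.10,0.01,0.86,1.62,36,71,1.22,0.02,0.71,1.76,72,1.53,0.02,1.17,2.02,ANOVA,***,< 0.001,***,< 0.001,+
serrata,serrata,Q122,41,82,1.09,0.01,0.85,1.29,37,72,1.18,0.01,0.90,1.55,74,1.21,0.02,0.95,1.94,ANOVA,***,< 0.001,ns,0.47,+
serrata,truncata,RGN179,38,76,1.12,0.01,0.93,1.35,36,72,1.05,0.01,0.92,1.31,72,1.27,0.01,0.99,1.55,ANOVA,***,< 0.001,***,< 0.001,+
seguyi,burlai,L6,34,68,1.07,0.01,0.89,1.26,32,64,1.20,0.02,0.96,1.46,64,1.13,0.01,0.90,1.36,ANOVA,**,0.001,**,0.001,-
seguyi,diplacantha,dip05860,39,78,1.15,0.01,0.97,1.70,40,74,1.22,0.02,0.85,1.59,74,1.23,0.01,0.85,1.51,ANOVA,***,< 0.001,ns,0.88,+
seguyi,greeni,14028-0712.00,35,70,1.05,0.01,0.79,1.27,37,74,1.11,0.01,0.79,1.37,73,1.14,0.02,0.88,1.62,ANOVA,***,< 0.001,ns,0.31,+
seguyi,jambulina,F76,36,70,1.04,0.01,0.84,1.25,36,72,1.00,0.01,0.82,1.30,71,1.07,0.01,0.88,1.26,ANOVA,ns,0.11,***,< 0.001,-
seguyi,malagassya,J6,37,73,1.10,0.01,0.79,1.48,35,70,1.14,0.02,0.86,1.47,70,1.07,0.01,0.76,1.31,ANOVA,ns,0.17,*,0.01,-
seguyi,nikananu,14028-0601.00,37,73,1.01,0.01,0.75,1.29,34,62,1.09,0.02,0.68,1.46,62,1.07,0.02,0.80,1.53,ANOVA,*,0.04,ns,0.72,-
seguyi,seguyi,K59,41,81,1.10,0.01,0.87,1.39,37,73,1.14,0.01,0.88,1.53,74,1.18,0.02,0.88,1.64,ANOVA,**,0.002,ns,0.4,-
seguyi,tsacasi,14028-0701.00,33,65,1.06,0.01,0.84,1.45,32,64,1.20,0.02,0.87,1.58,64,1.17,0.01,0.92,1.44,ANOVA,***,< 0.001,ns,0.46,+
seguyi,vulcana,14028-0711.00,38,75,1.07,0.01,0.88,1.69,34,68,1.01,0.01,0.83,1.18,68,1.07,0.01,0.89,1.41,ANOVA,ns,0.96,***,< 0.001,-
parvula,kanapiae,14028-0541.00,35,69,1.11,0.02,0.87,1.57,34,67,1.10,0.01,0.92,1.37,67,1.15,0.01,0.90,1.55,ANOVA,ns,0.14,**,0.01,-
parvula,parvula,ML11218,34,68,1.21,0.01,0.94,1.47,36,70,1.28,0.02,1.00,1.62,70,1.23,0.01,0.98,1.53,ANOVA,ns,0.54,ns,0.07,-
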