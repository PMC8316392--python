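group,species,strain,N,mean,sem,min,max,letters,ingroup
montium,baimaii,ML11023,6,3.1,0.2,2,4,bcde,True
montium,fengkainensis,XT33,6,2.5,0.3,2,4,cde,True
montium,lacteicornis,IRUR20,6,3.4,0.4,2,6,bcde,True
montium,pectinifera,OGS98m,6,2.2,0.2,1,3,e,True
montium,trapezifrons,Bavi31,6,2.4,0.2,2,4,cde,True
kikkawai,bocki,IR2-37,6,3.3,0.3,2,5,bcde,True
kikkawai,kikkawai,OGH06-01,14,2.9,0.2,2,5,bcde,True
kikkawai,leontia,AO-2,5,2.7,0.2,2,3,cde,True
kikkawai,ogumai,RGN3,6,2.3,0.2,1,4,cde,True
kikkawai,ohnishii,ML45,6,2.7,0.2,2,4,cde,True
punjabiensis,watanabei,14028-0531.02,6,2.3,0.2,1,3,cde,True
serrata,barbarae,ML11213,5,5.3,0.5,3,7,a,True
serrata,birchii,14028-0521.00,5,2.4,0.2,2,4,cde,True
serrata,mayri,14028-0591.00,6,3.6,0.2,3,4,bc,True
serrata,serrata,Q122,6,2.1,0.1,1,3,e,True
serrata,truncata,RGN179,6,2.7,0.3,2,5,cde,True
seguyi,diplacantha,dip05860,6,3.0,0.5,1,6,bcde,True
seguyi,greeni,14028-0712.00,6,3.6,0.4,2,5,bcd,True
seguyi,tsacasi,14028-0701.00,6,2.2,0.2,1,3,de,True
outgroup,melanogaster,Canton-S,5,4.2,0.2,3,5,ab,False
outgroup,subobscura,zenez,6,5.1,0.2,3,8,a,False
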