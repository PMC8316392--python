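(((((kanapiae:1,parvula:1):1,((((seguyi:1,vulcana:1):1,(nikananu:1,malagassya:1):1):1,((burlai:1,jambulina:1):1,(diplacantha:1,(greeni:1,tsacasi:1):1):1):1):1,((((punjabiensis:1,watanabei:1):1,orosa:1):1,(((barbarae:1,mayri:1):1,(truncata:1,cauverii:1):1):1,((serrata:1,(birchii:1,bunnanda:1):1):1,bicornuta:1):1):1):1,(((kikkawai:1,(leontia:1,bocki:1):1):1,(lini:1,(ogumai:1,ohnishii:1):1):1):1,((((auraria:1,subauraria:1):1,(biauraria:1,triauraria:1):1):1,((rufa:1,tani:1):1,(asahinai:1,neoasahinai:1):1):1):1,(((baimaii:1,pseudobaimaii:1):1,trapezifrons:1):1,(fengkainensis:1,(lacteicornis:1,pectinifera:1):1):1):1):1):1):1):1):1,(melanogaster:1,(erecta:1,yakuba:1):1):1):1,(subobscura:1,affinis:1):1):1,(virilis:1,mercatorum:1):1);
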