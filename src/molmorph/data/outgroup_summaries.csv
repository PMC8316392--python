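species,sex,segment,mean,sem
melanogaster,male,A5,1.71,0.03
melanogaster,male,A4,1.00,0.01
melanogaster,female,A5,0.99,0.01
subobscura,male,A5,1.93,0.04
subobscura,female,A5,1.12,0.02
subobscura,male,A4,2.13,0.04
affinis,male,A5,1.34,0.02
affinis,male,A4,1.32,0.02
affinis,female,A5,1.13,0.01
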