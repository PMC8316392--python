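species,group,state
melanogaster,melanogaster,1
erecta,melanogaster,0
yakuba,melanogaster,0
subobscura,obscura,1
affinis,obscura,1
virilis,virilis,0
mercatorum,repleta,0
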