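section,g_na,g_k,g_ca,g_kca,g_l
dendrite,50,35,1,0.11,0.5
soma,70,35,0.75,0.05,0.5
soma_AIS,175,90,0.75,0.05,0.5
AIS,350,175,0.75,0.05,0.5
axon,100,50,0.75,0.25,0.5
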