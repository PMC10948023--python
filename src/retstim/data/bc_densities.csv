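section,g_ca,g_l
dendrite,0,0.5
soma,0,0.5
axon,0,0.5
terminal,0.5,0.5
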