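name,stiffness_K,poisson
quadriceps_tendon,1350,0.3
patellar_tendon,2000,0.3
lateral_retinaculum,2,0.3
native_mpfl,12,0.3
semitendinosus,100,0.3
gracilis,80,0.3
mqtfl_semitendinosus,100,0.3
tibialis_posterior_allograft,513,0.3
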