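bundle,flexion_deg,length_mm,tension
anatomic,0,60.2,+
anatomic,30,57.9,+
anatomic,40,57.7,ref
anatomic,60,57.3,*
anatomic,90,55.6,*
anatomic,120,50.7,*
amt_superior,0,61.1,+
amt_superior,30,60.9,+
amt_superior,40,60.8,ref
amt_superior,60,60.7,*
amt_superior,90,60.4,*
amt_superior,120,55.8,*
amt_inferior,0,58.3,+
amt_inferior,30,60.1,+
amt_inferior,40,60.8,ref
amt_inferior,60,62.1,*
amt_inferior,90,62.2,*
amt_inferior,120,57.0,*
mqtfl,0,65.0,+
mqtfl,30,63.0,+
mqtfl,40,62.7,ref
mqtfl,60,62.0,*
mqtfl,90,62.0,*
mqtfl,120,62.0,*
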