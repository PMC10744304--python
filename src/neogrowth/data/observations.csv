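material,shape,d_mm,day,filling_pct
HAp,pooled,0.7,10,38.0
HAp,pooled,0.7,21,93.42
HAp,pooled,1.0,10,30.0
HAp,pooled,1.0,21,76.83
TCP,pooled,0.7,10,49.58
TCP,pooled,0.7,21,86.67
TCP,pooled,1.0,10,33.42
TCP,pooled,1.0,21,69.33
BCP,pooled,0.7,10,23.67
BCP,pooled,0.7,21,59.83
BCP,pooled,1.0,10,17.08
BCP,pooled,1.0,21,48.08
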