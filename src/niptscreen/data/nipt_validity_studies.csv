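study,approach,tp,fn,tn,fp
Ehrich et al 2011,whole-genome,39,0,410,1
Palomaki et al 2011,whole-genome,212,3,1471,3
Bianchi et al 2012,whole-genome,89,0,404,0
Ashoor et al 2012,targeted,50,0,297,0
Sparks et al 2012,targeted,36,0,123,0
Norton et al 2012,targeted,81,0,2888,1
Futch et al 2013,whole-genome,154,2,5515,1
Liang et al 2013,whole-genome,40,0,372,0
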