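rsid,gene,effect_allele,pooled_or
rs7903146,TCF7L2,T,1.40
rs10811661,CDKN2A/B,T,1.22
rs10946398,CDKAL1,C,1.18
rs1111875,HHEX,C,1.16
rs5219,KCNJ11,T,1.13
rs11671664,GIPR,A,1.10
rs780094,GCKR,C,1.08
rs1387153,MTNR1B,T,1.07
rs340874,PROX1,C,1.07
rs10830963,MTNR1B,G,1.06
rs2191349,DGKB-TMEM195,T,1.06
rs174550,FADS1,T,1.04
rs10885122,ADRA2A,G,1.04
rs11071657,C2CD4B,A,1.03
rs7034200,GLIS3,A,1.03
rs560887,G6PC2,T,1.03
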