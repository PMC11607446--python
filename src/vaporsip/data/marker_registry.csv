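marker,group,in_gram_positive_sum,in_multivariate_fungi
18:1w9c,fungi,false,true
"18:2w6,9",fungi,false,true
16:1w5,amf,false,true
10Me16:0,actinobacteria,true,false
10Me17:0,actinobacteria,true,false
10Me18:0,actinobacteria,true,false
i15:0,gram_positive,true,false
a15:0,gram_positive,true,false
i16:0,gram_positive,true,false
i17:0,gram_positive,true,false
a17:0,gram_positive,true,false
16:1w7,gram_negative,false,false
cy17:0,gram_negative,false,false
cy19:0,gram_negative,false,false
18:1w9t,general,false,false
16:0,general,false,false
17:0,general,false,false
18:0,general,false,false
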