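fatty_acid,group,c_plfa
i15:0,gram_positive,15
a15:0,gram_positive,15
i16:0,gram_positive,16
i17:0,gram_positive,17
16:1w7,gram_negative,16
18:1w7,gram_negative,18
cy17:0,gram_negative,17
cy19:0,gram_negative,19
15:0,general_bacteria,15
17:0,general_bacteria,17
10Me17:0,actinobacteria,18
10Me18:0,actinobacteria,19
17:1w8c,methanotroph,17
19:1w8,methanotroph,19
"18:2w6,9",fungi,18
16:1w5,amf,16
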