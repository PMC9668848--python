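allometry_key,a_ug,b
mite,17.0,2.50
collembola,4.0,2.30
annelid,8.0,2.00
insect,11.0,2.60
myriapod,9.0,2.20
arachnid,20.0,2.40
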