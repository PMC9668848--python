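taxon,trophic_group,allometry_key
collembola,detritivorous_collembola,collembola
oribatida,detritivorous_mites,mite
astigmata,detritivorous_mites,mite
prostigmata_detritivorous,detritivorous_mites,mite
enchytraeidae,annelids,annelid
lumbricidae_juvenile,annelids,annelid
coleoptera_detritivorous,other_detritivores,insect
diptera_larvae,other_detritivores,insect
myriapoda_detritivorous,other_detritivores,myriapod
hemiptera,herbivores,insect
thysanoptera,herbivores,insect
mesostigmata,predaceous_mites,mite
prostigmata_predaceous,predaceous_mites,mite
arachnida,predaceous_fauna,arachnid
chilopoda,predaceous_fauna,myriapod
coleoptera_predatory,predaceous_fauna,insect
symphyla,predaceous_fauna,myriapod
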