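gene_id	description	condition
CmoCh17G009900	Photosystem II CP47 reaction center protein	P-WS
CmoCh15G006560	Photosystem II CP47 reaction center protein	P-WS
CmoCh10G011100	Photosystem II protein D2	P-WS
CmoCh12G006890	Photosystem II protein D1	P-WW
CmoCh00G000540	Photosystem II CP43 reaction center protein	P-WW
CmoCh11G012220	Photosystem I p700 chlorophyll a apoprotein A2	P-WS
CmoCh11G012200	Photosystem I P700 chlorophyll a apoprotein A1	P-WS
CmoCh17G010900	Apocytochrome f	P-WW
CmoCh00G000730	Photosystem I P700 chlorophyll a apoprotein A1	P-WW
CmoCh00G000560	Photosystem I P700 chlorophyll a apoprotein A1	P-WW
CmoCh16G005090	Chloroplast photosystem II light-inducible protein	P-WS
CmoCh15G004580	Photosystem I light-harvesting chlorophyll a/b-binding protein	P-WS
CmoCh11G012210	Photosystem I P700 chlorophyll a apoprotein A1	P-WS
CmoCh00G000550	Photosystem I p700 chlorophyll a apoprotein A2	P-WS
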