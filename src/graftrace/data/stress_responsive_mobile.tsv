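gene_id	description	go_term
CmoCh01G015950.1	Glucan endo-1,3-beta-glucosidase	Carbohydrate metabolic process, defense response, cell wall
CmoCh04G020740.1	ATP synthase subunit a	ATP synthesis coupled proton transport
CmoCh06G000970.1	DnaJ-like subfamily B member 8	Protein folding
CmoCh06G007160.1	Heat shock protein 81.4	Response to stress
CmoCh07G010280.1	70-kDa heat shock protein (HSP70)	Oxidation-reduction process
CmoCh09G000520.1	High mobility group B protein 2 (HMGB)	Chloroplast
CmoCh12G001440.1	Chaperone protein DnaJ	Protein domain specific binding
CmoCh15G009410.1	alpha-Glucosidase	Sucrose metabolic process
CmoCh15G012980.1	Transmembrane water channel protein	Transporter activity
CmoCh18G001250.1	Serine/threonine-protein kinase-transforming protein (STK)	Protein phosphorylation
CmoCh18G002910.1	Ubiquitin	Cellular protein modification process
CmoCh16G009140.1	Ubiquitin	Cellular protein modification process
CmoCh03G005460.1	Ubiquitin	Cellular protein modification process
CmoCh14G002590.1	Peroxiredoxin	Peroxidase activity
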