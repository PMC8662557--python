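otu_id	lineage	support
OTU_186	Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis cinerea	99
OTU_63	Fungi;Mucoromycota;Mucoromycetes;Mucorales;Rhizopodaceae;Rhizopus;Rhizopus arrhizus	87
OTU_3	Fungi;Mucoromycota;Mucoromycetes;Mucorales;Mucoraceae;Mucor;Mucor circinelloides	80
OTU_116	Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus	89
OTU_192	Fungi;Basidiomycota;Exobasidiomycetes;Microstromatales;Tilletiopsidaceae;Tilletiopsis;Tilletiopsis washingtonensis	99
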