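Feature ID	Taxon	Confidence
OTU_186	d__Fungi;p__Basidiomycota;c__Agaricomycetes;o__Agaricales;f__Psathyrellaceae;g__Coprinopsis;s__Coprinopsis_strossmayeri	1.00
OTU_63	d__Fungi;p__Mucoromycota;c__Mucoromycetes;o__Mucorales;f__Cunninghamellaceae;g__Cunninghamella;s__Cunninghamella_bertholletiae	0.93
OTU_3	d__Fungi;p__Mucoromycota;c__Mucoromycetes;o__Mucorales;f__Mucoraceae;g__Mucor	0.89
OTU_116	d__Fungi;p__Basidiomycota;c__Agaricomycetes;o__Hymenochaetales;f__Hymenochaetaceae;g__Phellinus	0.95
OTU_192	d__Fungi;p__Basidiomycota;c__Exobasidiomycetes;o__Microstromatales;f__Microstromataceae;g__Microstroma	1.00
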