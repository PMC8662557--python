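OTU_186	-	Fungi	domain	1.0	Basidiomycota	phylum	1.0	Agaricomycetes	class	0.98	Agaricales	order	0.95	Psathyrellaceae	family	0.9	Coprinopsis	genus	0.73
OTU_63	-	Fungi	domain	1.0	Mucoromycota	phylum	1.0	Mucoromycetes	class	1.0	Mucorales	order	1.0	Rhizopodaceae	family	1.0	Rhizopus	genus	1.0
OTU_3	-	Fungi	domain	1.0	Mucoromycota	phylum	1.0	Mucoromycetes	class	1.0	Mucorales	order	1.0	Mucoraceae	family	1.0	Mucor	genus	1.0
OTU_116	-	Fungi	domain	1.0	Basidiomycota	phylum	1.0	Agaricomycetes	class	0.95	Hymenochaetales	order	0.9	Schizoporaceae	family	0.8	Lagarobasidium	genus	0.62
OTU_192	-	Fungi	domain	1.0	Basidiomycota	phylum	1.0	Exobasidiomycetes	class	0.99	Microstromatales	order	0.97	Microstromataceae	family	0.95	Microstroma	genus	0.46
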