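term_id	supercluster	subcluster
GO:0001	development	epithelium development
GO:0002	development	thyroid development
GO:0003	development	lung development
GO:0004	proliferation	general
GO:0005	proliferation	cell cycle
GO:0006	transport	general
GO:0007	transport	anion transport
GO:0008	signaling	cAMP
GO:0009	signaling	growth factors
GO:0010	metabolism	hormone
GO:0002	metabolism	hormone
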