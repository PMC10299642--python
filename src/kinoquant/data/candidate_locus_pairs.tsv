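gene	locus
ANKEF1	n/a
ODF3L2	DFNB72
ODF3L2	DFNA57
SAXO2	DFNA30
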