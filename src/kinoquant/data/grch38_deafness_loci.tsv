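label	region
DFNB72	19:4949401-6113471
DFNA57	19:7806762-18232460
DFNA30	15:87053920-94168232
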