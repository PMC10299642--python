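label	region
ANKEF1	20:10034987-10058303
ODF3L2	19:463346-474880
SAXO2	15:82262818-82284927
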