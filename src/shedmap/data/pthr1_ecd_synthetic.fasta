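>PTHR1_ECD_SYNTHETIC synthetic surrogate ectodomain; embeds the identifying peptides EVLQRPASIME (54-64) and SDKGWTSASTSGKPRK (65-80) at receptor-numbering coordinates; flanking sequence is random, NOT the canonical receptor sequence
IHFTQKQSVKNWYPHEINMWLDTWRQYVLWYHLREYAIWNDYSCWDDDWPCMREVLQRPA
SIMESDKGWTSASTSGKPRKQGKWEERPPIQLLNGKTMYPYVAIPLPPAYCQNPHTLPTF
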