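# Neoplasm stems used for condition screening (plain case-insensitive substrings).
neopl	substring
cancer	substring
malignan	substring
tumor	substring
carcino	substring
onco	substring
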