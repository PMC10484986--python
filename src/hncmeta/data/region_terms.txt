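# Head-and-neck region strings (plain case-insensitive substrings).
head	substring
neck	substring
mouth	substring
oral cavity	substring
pharynx	substring
larynx	substring
nose	substring
paranasal	substring
salivary	substring
uadt	substring
upper aerodigestive tract	substring
gingiva	substring
otorinolar	substring
tongue	substring
tonsil	substring
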