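# HPV term list (MeSH-derived strings). Multi-word entries match as literal
# substrings after whitespace normalization; bare "hpv" is listed both as a
# whole word and as a substring so forms like HPV16 / HPV-positive match.
human papillomavirus	substring
hpv human papillomavirus	substring
alphapapillomaviruses	substring
hpv human papillomaviruses	substring
papillomavirus, human	substring
hpv	word
hpv	substring
human papillomaviruses, hpv	substring
papillomaviruses, human	substring
human papillomaviruses	substring
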