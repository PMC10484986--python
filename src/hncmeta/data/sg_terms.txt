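# Sex/gender term list: one entry per line, "term<TAB>mode".
# Modes: word = whole-word, stem = word-prefix stem, substring = anywhere.
sex	word
gender	word
woman	word
women	word
man	word
men	word
female	word
females	word
male	word
males	word
girl	word
girls	word
boy	word
boys	word
pregnan	stem
transg	stem
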