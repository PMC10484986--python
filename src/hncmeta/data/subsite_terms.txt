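# Condition strings marking HPV-relevant subsites (oral cavity / pharynx / larynx).
oral cavity	substring
pharyn	substring
laryn	substring
tonsil	substring
base of tongue	substring
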