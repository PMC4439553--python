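name	taxon_id
rattus norvegicus	10116
rat	10118
cat	9685
rhesus monkey	9544
rabbit	9986
human	9606
macaca fascicularis	9541
mouse	10090
chicken	9031
guinea-pig	10141
guinea pig	10141
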