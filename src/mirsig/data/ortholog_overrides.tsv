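mouse	human
mmu-miR-203-3p	miR-203a-5p
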