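# p53-MDM2 negative-feedback loop, external input dna_dsb fixed to 1 (DNA damage)
targets, factors
ATM, !WIP1 & 1
p53, ATM & !MDM2
WIP1, p53
MDM2, !ATM & (p53 | WIP1)
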