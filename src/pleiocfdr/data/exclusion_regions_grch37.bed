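chr6	25119105	33854733
chr8	7199999	12500000
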