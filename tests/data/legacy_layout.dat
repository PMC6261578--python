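dose time ncells count donor
0.0 1h 500 80 D1
0.5 1h 500 3100 D1
1.0 1h 500 6400 D2
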