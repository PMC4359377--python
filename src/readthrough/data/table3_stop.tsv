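stop	frequency
TAA	0.1928
TAG	0.3373
TGA	0.4699
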