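>MT-TT rCRS:15888-15953 tRNA-Thr gene segment, forward strand, 1-based inclusive
GTCCTTGTAGTATAAACTAATACACCAGTCTTGTAAACCGGAGATGAAAACCTTTTTCCAAGGACA
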