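pattern	n_introns
heterogeneous	2993
homogeneous_tumor	1610
homogeneous_normal	205
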