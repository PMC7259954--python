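analysis,row,bound_or_outside,unbound_or_inside
nucleotide_vs_rmsd,beyond_0.6A,1,8
nucleotide_vs_rmsd,within_0.6A,84,21
duty_vs_state,low_duty_unliganded,8,12
duty_vs_state,high_duty_unliganded,0,9
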