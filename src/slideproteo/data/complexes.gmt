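MCM_COMPLEX	MCM2-7 replicative helicase; stoichiometric co-expression probe	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7
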