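species	genome_size	mtpt_total_bp
C_carlesii	592702	7086
Ca_henryi	379929	10608
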