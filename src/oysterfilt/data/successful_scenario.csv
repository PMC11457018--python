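label,mean_sh_mm,density_per_m2
spat,16,61
seed,56,125
market,98,34
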