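# Default simulation overrides for `msilike simulate --config ...`.
# Keys map onto SimulationConfig; anything omitted keeps the package
# default (188 patients, 24 MSI-H, published-style clinical marginals,
# logit-normal TIL distributions, packaged synthetic gene frequencies).
n_patients: 188
n_positive: 24
msi_like_fraction: 0.15
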