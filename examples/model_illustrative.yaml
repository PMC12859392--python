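schema_version: 1
theta_ke: 0.08
theta_V: 75.0
ka: 3.43
beta_crcl: 0.35
beta_flu: 0.7
beta_age: 0.8
crcl_ref: 120.0
age_ref: 5.7
omega_ke: 0.4
omega_V: 0.35
sigma_add: 1.5
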