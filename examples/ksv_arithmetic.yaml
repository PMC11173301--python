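# Derived quenching quantities from measured Stern-Volmer constants:
# Kq = Ksv/tau (tau = 5 ns) and Kd = 1/Ksv, plus the mechanism call
# against the 1e10 L mol^-1 s^-1 diffusion limit.
output_dir: arithmetic_out
sv_arithmetic:
  tau_s: 5.0e-9
  threshold: 1.0e+10
  ksv_values:
    caf_low: 117050.0
    caf_high: 13780.0
    m16omc_low: 131160.0
    m16omc_high: 24690.0
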