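# Demo pipeline: synthetic datasets for every analysis stage.
seed: 17
output_dir: demo_out
datasets:
  - name: sv_noiseless
    generator:
      kind: sv
      params: {ksv: 117050.0, f0: 1000.0, noise_cv: 0.0}
    analyses: [sv, lehrer]
  - name: two_site
    generator:
      kind: two_site
      params: {kd1: 5.0e-8, q1: 0.45, kd2: 4.0e-5, q2: 0.5, noise_cv: 0.01}
    analyses: [segmented]
  - name: cd_bound
    generator:
      kind: cd
      params: {fractions: [0.68, 0.16, 0.16], noise_sd: 0.2}
    analyses: [cd]
  - name: melt_caf
    generator:
      kind: melt
      params: {tm_C: 53.84, dh_app: 3.0e+5, noise_cv: 0.02}
    analyses: [melt]
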