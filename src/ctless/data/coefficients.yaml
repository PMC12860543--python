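# Predefined attenuation coefficients (cm^-1) at the Tc-99m photopeak for the
# six attenuation regions, plus population statistics (mean, sd) of the
# per-region coefficients used to jitter synthetic cohorts.
regions:
  - name: skin_adipose
    mu: 0.13
    population_mean: 0.1339
    population_sd: 0.0029
  - name: muscles_organs
    mu: 0.16
    population_mean: 0.1604
    population_sd: 0.0022
  - name: lungs
    mu: 0.03
    population_mean: 0.0344
    population_sd: 0.0035
  - name: bones
    mu: 0.22
    population_mean: 0.2156
    population_sd: 0.0048
  - name: patient_table
    mu: 0.09
    population_mean: 0.0884
    population_sd: 0.0045
  - name: background
    mu: 0.0
    population_mean: 0.0
    population_sd: 0.0
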