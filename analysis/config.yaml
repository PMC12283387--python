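# Flagship synthetic dataset for the analysis scripts: six studies, three
# continental ancestry groups, 20,000 persons, generator-default effect
# sizes (response model seeded from the published demographic and PGS
# coefficients).
seed: 20260
studies:
  - {study_id: S1, ancestry_mix: {EUR: 1.0}, n_individuals: 4000}
  - {study_id: S2, ancestry_mix: {EUR: 1.0}, n_individuals: 3000}
  - {study_id: S3, ancestry_mix: {EUR: 1.0}, n_individuals: 3000}
  - {study_id: S4, ancestry_mix: {EUR: 0.5, AFR: 0.3, AMR: 0.2}, n_individuals: 4000}
  - {study_id: S5, ancestry_mix: {EUR: 0.4, AFR: 0.4, AMR: 0.2}, n_individuals: 3000}
  - {study_id: S6, ancestry_mix: {EUR: 0.6, AMR: 0.4}, n_individuals: 3000}
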