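# Default data-generating model for the simulated series of N-of-1 trials on
# Chronic Nonspecific Low Back Pain: daily pain (0-10) under two alternating
# exercise treatments, with sociodemographic and lifestyle covariates.
#
# Conventions interpreted by the simulator:
#   * instantaneous edges out of the treatment node act identically for both
#     treatments (an on-treatment level shift; with no untreated days this
#     creates no between-treatment contrast);
#   * lagged edges out of the treatment node are driven by the indicator of
#     treatment 2 on the lagged day and are active only in scenarios with the
#     activity interaction;
#   * the treatment -> pain edge marks the direct effect; its per-treatment
#     magnitudes come from the scenario configuration (defaults -2 and -4);
#   * the pain node's noise mean is the baseline pain intercept.
schema: 1
nodes:
  - name: demographics
    role: constant
    distribution: {kind: gaussian, params: [0.0, 1.0]}
  - name: education
    role: constant
    noise: {mean: 0.0, sd: 1.0}
    binary_threshold: 0.5
  - name: work
    role: constant
    noise: {mean: 0.0, sd: 1.0}
    binary_threshold: 0.0
  - name: prev_diagnosis
    role: constant
    noise: {mean: 0.0, sd: 1.0}
    binary_threshold: 0.8
  - name: chronic_diseases
    role: constant
    noise: {mean: 0.0, sd: 1.0}
    binary_threshold: 1.0
  - name: medication
    role: time_varying
    noise: {mean: 0.0, sd: 1.0}
    binary_threshold: 1.0
  - name: activity
    role: time_varying
    noise: {mean: 0.0, sd: 1.0}
  - name: stress
    role: time_varying
    noise: {mean: 0.0, sd: 1.0}
  - name: sleep_quality
    role: time_varying
    noise: {mean: 0.0, sd: 1.0}
  - name: treatment
    role: treatment
  - name: underlying_state
    role: time_varying
    observed: false
    distribution: {kind: wiener, params: [0.002, 0.03]}
  - name: pain
    role: outcome
    noise: {mean: 6.0, sd: 0.5}
edges:
  - {source: demographics, target: education, weight: 0.4}
  - {source: demographics, target: work, weight: 0.4}
  - {source: demographics, target: prev_diagnosis, weight: 0.3}
  - {source: demographics, target: chronic_diseases, weight: 0.3}
  - {source: demographics, target: medication, weight: 0.3}
  - {source: demographics, target: activity, weight: 0.3}
  - {source: treatment, target: stress, weight: -0.3}
  - {source: treatment, target: sleep_quality, weight: 0.3}
  - {source: treatment, target: activity, weight: 0.5, lag: 1}
  - {source: treatment, target: sleep_quality, weight: 0.3, lag: 1}
  - {source: treatment, target: pain, weight: -2.0}
  - {source: education, target: pain, weight: 0.2}
  - {source: work, target: pain, weight: -0.2}
  - {source: activity, target: pain, weight: 0.3}
  - {source: stress, target: pain, weight: 0.3}
  - {source: sleep_quality, target: pain, weight: -0.3}
  - {source: medication, target: pain, weight: -0.5}
  - {source: prev_diagnosis, target: pain, weight: 0.5}
  - {source: chronic_diseases, target: pain, weight: 0.5}
  - {source: underlying_state, target: pain, weight: 1.0}
carry_over:
  tau: [1.0, 1.0]
  gamma: [1.0, 1.0]
activity_interaction_weight: 0.0
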