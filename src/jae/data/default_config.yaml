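# Default pipeline configuration: clinical-protocol constants at a
# desk-scale audio rate (set fs_audio: 100000 for the original rate).
seed: 0
fs_audio: 25000
fs_motion: 50
band: [250, 10000]
lowpass_cutoff: 5
frame_len: 0.4
cycle_period: 4.0
threshold: 0.5
ridge: 1.0e-4
perm_cap: 1000
max_features: 20
registry: default
auto_clamp_band: true
cohort:
  n_jia: 25
  n_healthy: 18
  n_followup: 10
  cycles_per_recording: 10
  channels_per_subject: 4
  period_jitter: 0.02
  amplitude_jitter: 0.05
  noise_rms: 1.0
  jia_clicks_per_cycle: 6.0
  jia_click_amplitude: 8.0
  click_freq_range: [2000, 8000]
  click_decay: 0.003
  followup_attenuation: 5.0
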