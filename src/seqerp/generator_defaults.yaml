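# Generator defaults, version 1.
#
# These values define the study conditions the synthetic cohort emulates.
# Latency means/SDs are the published group statistics the behavioural
# pipeline is calibrated to recover; the remaining entries (within-trial
# noise, slope, rates) are generator choices documented in docs/methods.md.
version: 1
behaviour:
  offset_mean:            # ms, button release relative to first random trial
    terminated: 619.48
    regular: 532.81
    extended: 346.68
  offset_between_sd:      # ms, between-participant SD of condition means
    terminated: 96.55
    regular: 99.74
    extended: 219.35
  offset_within_sd: 150.0 # ms, within-participant trial-to-trial SD
  onset_mean_learned: 788.02  # ms, press relative to second sequence trial
  onset_between_sd: 168.0
  onset_within_sd: 150.0
  gain_mean:              # ms, new-cue minus learned-cue onset latency
    gain: 178.54
    no_gain: -45.40
  gain_sd:
    gain: 106.62
    no_gain: 82.24
  surprise_slope: -80.0   # ms per nat, extensions only, centred surprise
  # P(release at the cued "would-be" end | extended sequence).  Bounded
  # above by the published complete-design constraint: every participant
  # must typically retain at least one includable extended latency per
  # uncertainty level (the group analysis carries full df), which caps the
  # per-trial exclusion probability for the 4-trial low-uncertainty cell.
  premature_release_rate:
    gain: 0.12
    no_gain: 0.03
  miss_rate: 0.04
  fa_rate: 0.03           # per inter-sequence gap
erp:
  sampling_rate: 500.0    # Hz
  window: [-100.0, 600.0] # ms, half-open epoch
  noise_sd: 3.0           # uV sensor noise
  spatial_smoothing: 0.35 # Gaussian kernel scale in layout units
  participant_amp_sd: 0.15
  components:             # peak latencies in ms, amplitudes in uV
    P3b:      {center: Pz,  peak: {PE: 388.0, CP: 420.0}, width: 90.0, amplitude: 5.0,
               weights: {PE: 1.0, CP: 0.9}}
    N400:     {center: CPz, peak: {"*": 418.0}, width: 60.0, amplitude: -2.5,
               weights: {PE: 1.0}}
    P600:     {center: P6,  peak: {PE: 500.0, CP: 554.0}, width: 80.0, amplitude: 2.0,
               weights: {PE: 1.0, CP: 1.0, STD: -0.3}}
    early_frontal: {center: Fz, peak: {"*": 300.0}, width: 50.0, amplitude: 2.5,
               weights: {STD: 1.0, PE: 0.5, CP: 0.5}}
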