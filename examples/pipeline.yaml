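# chimotor pipeline configuration (defaults shown; all keys optional)
seed: 42
n_trajectories: 10
median_half_window_ms: 1.0   # running-median half window for denoising
min_plateau: 3               # minimum plateau length (frames)
s_threshold: 2.0             # counter-fit quality needed to accept a trace
mixture_components: 3
mixture_bin_nm: 0.3
dwell_bin_single_ms: 4.0
dwell_bin_convolution_ms: 2.0
scheme_estimator: censored_mle
sim:
  n_events: 60               # stepping events per trajectory
  frame_interval_ms: 0.5
  precision_peak_nm: 0.34    # peak of the pause-wise localization noise SD
  precision_spread_nm: 0.10
  step_ratios:
    forward: 0.693
    double: 0.142
    backward: 0.165
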