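# Run configuration for the mmpc CLI (--config).  All keys optional;
# values shown are the defaults.
input_space:
  lower: [0.0, 0.0]      # uM per input
  upper: [50.0, 10.0]
dose_times: [3, 8, 13, 18, 23]   # min post-stimulation
t_end: 30.0              # min, experiment end
n_pareto: 15             # Pareto points per interval (front resolution)
max_iter: 10             # weight-adaptation iterations per interval
tol_w: 1.0e-3            # weight-change convergence threshold
use_surrogate: true      # sparse-grid objective interpolation
surrogate_cfg:
  tol_abs: 0.01
  tol_rel: 0.01
  max_depth: 6
windowed_weights: false  # recalibrate over the whole time course at u
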