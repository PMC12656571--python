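"""Feature engineering, windowing and class weights on one recording.

Shows the 14-channel expansion (raw Euler/acceleration channels, their
first-order differences, and the two vector norms), the sliding-window
bookkeeping, and the balanced class weights that compensate the
breathing/noise imbalance during training.
"""

import imubreath as ib

spec = ib.SyntheticSpec(duration_s=120.0, sampling_rate_hz=33.0, seed=2)
rec, gt = ib.simulate_recording(spec)

fs = ib.engineer_features(rec)
print("feature channels:", ", ".join(ib.FEATURE_NAMES))

cfg = ib.PipelineConfig(window_size=100, step=10)  # 3 s windows, 0.3 s stride at 33 Hz
ws = ib.make_windows(fs, gt.annotation, cfg)
n_b, n_n = ws.counts()
n_u = len(ws) - n_b - n_n
print(f"{len(ws)} windows: {n_b} breathing, {n_n} noise, {n_u} unlabeled")
print("expected count per valid run:",
      ib.count_windows(rec.n_valid, cfg.window_size, cfg.step))

cw = ib.compute_class_weights(n_b, n_n)
print(f"class weights: breathing {cw.weight_breathing:.3f}, noise {cw.weight_noise:.3f}")
print("conservation: n_b*w_b + n_n*w_n =",
      n_b * cw.weight_breathing + n_n * cw.weight_noise, "= n_total =", cw.n_total)

# The minority class (noise) receives the larger weight, and the weighted
# counts always sum back to the total number of labeled windows.
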