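"""Architecture bookkeeping of the breathing classifier.

Prints the closed-form parameter count per layer, verifies it against a
brute-force tally over the instantiated weight tensors, and reports the
32-bit memory footprint — the numbers that make the model suitable for
microcontroller-class deployment.
"""

import imubreath as ib
from imubreath.crnn_model import ModelSpec

spec = ModelSpec()  # 14 input channels, conv 32@k5, conv 64@k5, LSTM 64, dense 32

conv1 = (spec.in_channels * spec.conv1_kernel + 1) * spec.conv1_filters
conv2 = (spec.conv1_filters * spec.conv2_kernel + 1) * spec.conv2_filters
lstm = 4 * ((spec.conv2_filters + spec.lstm_units) * spec.lstm_units + spec.lstm_units)
dense = spec.lstm_units * spec.dense_units + spec.dense_units
out = spec.dense_units + 1

print(f"conv1 : {conv1:7,d}")
print(f"conv2 : {conv2:7,d}")
print(f"lstm  : {lstm:7,d}")
print(f"dense : {dense:7,d}")
print(f"output: {out:7,d}")
print(f"total : {ib.count_trainable_parameters(spec):7,d} (closed form)")

net = ib.build_model(ModelSpec(window_size=100), seed=0)
print(f"tally : {net.n_parameters():7,d} (instantiated tensors; independent of window size)")
print(f"memory: {ib.memory_footprint_mb(spec):.2f} MB at 32-bit precision")

l1, p1, l2, p2 = ModelSpec(window_size=2000).sequence_lengths()
print(f"sequence into the LSTM for a 2000-sample window: {p2} steps")
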