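"""Tree-level defoliation rate from branch needle counts.

A sampled tree is scored by clipping standard branches from its upper,
middle and lower layers and counting needles in the 0/25/50/75/100 %
loss levels; the tree rate averages the three layer rates.
"""

import numpy as np

from crownedge import defoliation_rate

# rows: upper, middle, lower layer; columns: needle counts at
# 0 / 25 / 50 / 75 / 100 % needle loss
counts = np.array([
    [120,  80,  40,  10,   0],   # upper layer: mostly intact
    [ 40,  90,  70,  30,  10],   # middle layer: moderate loss
    [ 10,  30,  60,  80,  70],   # lower layer: heavy loss
])

layer_rates = counts @ np.array([0, 25, 50, 75, 100]) / counts.sum(axis=1)
for name, rate in zip(("upper", "middle", "lower"), layer_rates):
    print(f"{name:6s} layer defoliation: {rate:5.1f} %")
print(f"tree defoliation rate: {defoliation_rate(counts):.1f} %")
# > 60 % would classify this tree as severely damaged in most survey schemes
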