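"""Trade float precision for storage with Quantize and BitRound.

Quantize keeps ~d decimal digits by rounding to a power-of-two grid
(scale = 2^ceil(d*log2(10))), bounding the absolute error by half a grid
step; BitRound keeps a fixed number of mantissa bits, bounding the
*relative* error. Both zero out low-order mantissa bits, which is what
makes the compressed chunks smaller. The filters go into an array's codec
chain via a schema override, so precision is a per-field choice.
"""

import math

import numpy as np

from vczkit import bitround_values, mean_absolute_error, quantize_values

x = np.random.default_rng(1).random(1_000_000)

print(f"{'digits':>6s} {'scale':>8s} {'MAE':>12s} {'bound':>12s}")
for d in range(1, 8):
    keep = math.ceil(d * math.log2(10))
    q = quantize_values(x, d)
    mae = mean_absolute_error(x, q)
    bound = 0.5 * 2.0**-keep
    print(f"{d:>6d} {2**keep:>8d} {mae:>12.3e} {bound:>12.3e}")

xf = x[:100_000].astype("f4")
print(f"\n{'keep bits':>9s} {'MAE':>12s}")
for k in (3, 5, 10, 23):
    mae = mean_absolute_error(xf, bitround_values(xf, k))
    print(f"{k:>9d} {mae:>12.3e}")
print("\nkeep=23 (full single-precision mantissa) is the identity; "
      "the NaN sentinels for missing/fill pass through both filters "
      "with their payloads intact.")
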