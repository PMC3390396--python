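"""Dual-channel colocalization and centromere exclusion.

Two antibody channels detect the same underlying crossover sites with
channel-specific dropout and positional jitter; threshold matching then
yields asymmetric directional fractions. A point reference per chromosome
(the centromere) gives the fraction of foci located away from it.
"""

import numpy as np
import pandas as pd

from meiocross import coloc_fractions, fraction_outside_reference, simulate_dual_channel

rng = np.random.default_rng(9)
rows_a, rows_b, rows_ref = [], [], {}
for i in range(3000):
    base = np.sort(rng.uniform(0, 1, 3))
    a, b = simulate_dual_channel(base, rng=rng)  # default asymmetric dropout
    rows_a += [(f"c{i}", 0, "A", p) for p in a]
    rows_b += [(f"c{i}", 0, "B", p) for p in b]
    rows_ref[(f"c{i}", 0)] = 0.45  # centromere position

cols = ["cell_id", "bivalent_id", "channel", "position_frac"]
chan_a, chan_b = pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)

res = coloc_fractions(chan_a, chan_b, tolerance=0.01)
print(f"{100 * res.fraction_a_with_b:.1f}% of A foci contain a B focus "
      f"(n_A={res.n_a})")
print(f"{100 * res.fraction_b_with_a:.1f}% of B foci contain an A focus "
      f"(n_B={res.n_b})")

outside = fraction_outside_reference(chan_b, rows_ref, tolerance=0.022)
print(f"{100 * outside:.1f}% of B foci lie outside the centromere window")
print()
print("Asymmetric dropout reproduces the ~93%/~97.5% co-staining pattern;")
print("uniformly placed foci sit outside a 2.2%-of-SC window ~95.6% of the time.")
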