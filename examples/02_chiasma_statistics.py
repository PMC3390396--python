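"""Distributional statistics of per-cell chiasma counts.

Interference makes wild-type chiasma counts much less variable than a
Poisson with the same mean, so the goodness-of-fit test rejects; residual
class II chiasmata in pathway mutants are Poisson-like and fit. The
pooled t-test, retention percentage and pathway fraction reproduce the
classical summary arithmetic.
"""

from meiocross import (
    cell_summaries_from_table,
    class1_fraction,
    genotype_config,
    poisson_gof,
    pooled_t_test,
    retention_percent,
    simulate_dataset,
)
from meiocross.simulate import WT_CHIASMA_CALIBRATED_MU

wt_cells, _ = simulate_dataset(
    genotype_config("WT", n_cells=250, seed=11, class1_mu=WT_CHIASMA_CALIBRATED_MU)
)
mut_cells, _ = simulate_dataset(genotype_config("hei10", n_cells=130, seed=12))

for label, cells in [("WT", wt_cells), ("hei10", mut_cells)]:
    counts = cell_summaries_from_table(cells)["chiasma_count"]
    gof = poisson_gof(counts.tolist())
    verdict = "deviates from" if gof.p_value < 0.01 else "consistent with"
    print(f"{label:>6}: mean {counts.mean():5.2f}, chi2[{gof.df}] = {gof.chi2:6.1f}, "
          f"p = {gof.p_value:.3g}  -> {verdict} Poisson")

tt = pooled_t_test(6.5, 2.1, 130, 2.1, 1.3, 121)
print(f"\nhei10 vs mer3hei10 (published summaries): t[{tt.df}] = {tt.t:.1f}, p = {tt.p_value:.2g}")
print(f"chiasma retention in hei10: {retention_percent(6.5, 20.7):.1f}% of wild type")
print(f"class I share of all crossovers: {class1_fraction(24.3, 28.3):.1f}%")
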