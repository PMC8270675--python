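"""TMM normalization and moderated t-statistics for hES9S vs WT.

Simulates ~8,000 windows of negative-binomial counts with unequal depths
and a skewed composition, computes TMM factors, fits the voom-limma stage
and shows how the planted enrichment separates in the moderated t.
"""

import numpy as np

from velcroseq import SimulationConfig, generate_counts
from velcroseq.normalize import tmm_factors
from velcroseq.diffbind import run_diffbind
from velcroseq.windows import filter_low_count

config = SimulationConfig(seed=3, n_genes=1000, windows_per_gene=8,
                          planted_nonnull_fraction=0.157,
                          library_sizes=(1.0, 1.2, 0.8, 1.1, 0.9, 1.3),
                          composition_skew_fraction=0.05)
matrix, truth = generate_counts(config)
matrix = filter_low_count(matrix, 30)

factors = tmm_factors(matrix)
print("TMM factors (geometric mean 1):")
print(factors.factors.round(3).to_string())

result = run_diffbind(matrix, factors)
t = result.table["t"]
enriched = truth.windows.loc[matrix.counts.index, "enriched"]
print(f"\nvariance prior: d0 = {result.d0:.1f}, s0^2 = {result.s0_squared:.3f}")
print(f"median moderated t  (null windows): {t[~enriched].median():+.2f}")
print(f"median moderated t (planted windows): {t[enriched].median():+.2f}")
# Planted windows (2^2 = 4x more material bound to hES9S ribosomes) sit far
# in the right tail; null windows center near zero.
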