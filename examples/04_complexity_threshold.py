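"""Library-complexity threshold from the duplication-rate simulation.

Samples reads with replacement from virtual pools of C genome copies
(complexity C in 0.1-100) at depths 0.1-1x and tabulates the duplicate
fraction.  At 0.1x depth a 2% duplication ceiling is first met at
complexity 3 — the minimum input complexity for reliable shallow
sequencing.  Size selection discards ~90% of the input DNA, so this floor
is what makes the enrichment protocol viable.
"""

import numpy as np

from ffenrich import GenomeModel, duplication_grid, min_complexity, snp_complexity

genome_size = GenomeModel.scaled_hg19().total_length
grid = duplication_grid(genome_size, seed=4, reps=30)

pivot = grid.pivot(index="complexity", columns="depth",
                   values="duplication_rate")
print("duplication rate (rows: complexity, columns: depth)")
print((100 * pivot).round(2).to_string())
print(f"\nminimum complexity at 0.1x depth under a 2% ceiling: "
      f"{min_complexity(grid, depth=0.1, rate_ceiling=0.02)}")

counts = np.random.default_rng(5).poisson(7, 300)
result = snp_complexity(counts)
print(f"\nSNP-panel example: {result.unique_snp_covering_reads} unique "
      f"covering reads over {result.panel_size} SNPs -> "
      f"complexity {result.complexity:.2f} (adequate: >= 3)")
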