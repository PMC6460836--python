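"""Library-complexity statistic and duplication-rate simulation.

DNA complexity of a captured SNP panel is the number of unique panel-SNP-
covering reads divided by the panel size; it proxies how many distinct
genome copies entered the library.  The duplication simulation motivates a
minimum-complexity threshold: a virtual pool of ``M = C * genome / read_len``
distinct molecules (C genome copies) is sampled with replacement at depth
``d`` (``n = d * genome / read_len`` draws) and the duplicate fraction
``1 - distinct/n`` is recorded.  Its expectation has the closed form

    E[rate] = 1 - M * (1 - (1 - 1/M)^n) / n,

which is ~ d / (2C) for shallow sampling, independent of the genome size —
so the complexity threshold found on a scaled genome transfers to the full
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PANEL_SIZE = 300
DEFAULT_READ_LENGTH = 150
DEFAULT_C_GRID = (0.1, 0.3, 1.0, 2.0, 3.0, 5.0, 10.0, 30.0, 100.0)
DEFAULT_D_GRID = (0.1, 0.2, 0.5, 1.0)
DEFAULT_RATE_CEILING = 0.02


@dataclass(frozen=True)
class ComplexityResult:
    unique_snp_covering_reads: int
    panel_size: int
    complexity: float


def snp_complexity(
    per_snp_unique_reads, panel_size: int = DEFAULT_PANEL_SIZE
) -> ComplexityResult:
    """DNA complexity = unique SNP-covering reads / SNP panel size."""
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    counts = np.asarray(per_snp_unique_reads)
    if np.any(counts < 0):
        raise ValueError("per-SNP read counts must be non-negative")
    total = int(counts.sum())
    return ComplexityResult(
        unique_snp_covering_reads=total,
        panel_size=panel_size,
        complexity=total / panel_size,
    )


@dataclass(frozen=True)
class DupSimResult:
    complexity: float
    depth: float
    read_length: int
    genome_size: int
    pool_size: int
    n_draws: int
    duplication_rate: float      # Monte-Carlo mean over replicates
    rate_sd: float
    expected_rate: float         # closed-form expectation
    replicates: int


def expected_duplication_rate(pool_size: int, n_draws: int) -> float:
    """Closed form 1 - M (1 - (1 - 1/M)^n) / n for sampling with replacement."""
    m, n = float(pool_size), float(n_draws)
    if m <= 0 or n <= 0:
        raise ValueError("pool size and draw count must be positive")
    distinct = m * -np.expm1(n * np.log1p(-1.0 / m)) if m > 1 else 1.0
    return float(1.0 - distinct / n)


def simulate_duplication(
    complexity: float,
    depth: float,
    genome_size: int,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int | None = None,
    reps: int = 50,
    rng: np.random.Generator | None = None,
) -> DupSimResult:
    """Monte-Carlo duplication rate for one (complexity, depth) condition.

    Molecules are abstract identifiers (duplication = re-drawing the same
    source molecule), so the simulation is O(draws).  Fractional complexity
    C < 1 means a pool covering only a fraction C of the genome.
    """
    if complexity <= 0 or depth <= 0:
        raise ValueError("complexity and depth must be positive")
    pool = round(complexity * genome_size / read_length)
    if pool <= 0:
        raise ValueError("empty molecule pool (complexity * genome too small)")
    n = max(1, round(depth * genome_size / read_length))
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = np.empty(reps)
    for i in range(reps):
        draws = rng.integers(0, pool, n)
        rates[i] = 1.0 - len(np.unique(draws)) / n
    return DupSimResult(
        complexity=complexity, depth=depth, read_length=read_length,
        genome_size=genome_size, pool_size=pool, n_draws=n,
        duplication_rate=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if reps > 1 else 0.0,
        expected_rate=expected_duplication_rate(pool, n),
        replicates=reps,
    )


def duplication_grid(
    genome_size: int,
    c_values=DEFAULT_C_GRID,
    d_values=DEFAULT_D_GRID,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int | None = None,
    reps: int = 50,
) -> pd.DataFrame:
    """Duplication rates over a (complexity x depth) grid."""
    c_values, d_values = list(c_values), list(d_values)
    if not c_values or not d_values:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    rows = []
    for c in c_values:
        for d in d_values:
            r = simulate_duplication(c, d, genome_size,
                                     read_length=read_length, rng=rng, reps=reps)
            rows.append({
                "complexity": c, "depth": d,
                "duplication_rate": r.duplication_rate,
                "rate_sd": r.rate_sd, "expected_rate": r.expected_rate,
                "pool_size": r.pool_size, "n_draws": r.n_draws,
            })
    return pd.DataFrame(rows)


def min_complexity(
    grid: pd.DataFrame,
    depth: float,
    rate_ceiling: float = DEFAULT_RATE_CEILING,
) -> float:
    """Smallest grid complexity whose mean rate is within the ceiling at ``depth``."""
    at_d = grid.loc[np.isclose(grid["depth"], depth)]
    if at_d.empty:
        raise ValueError(f"depth {depth} not present in grid")
    ok = at_d.loc[at_d["duplication_rate"] <= rate_ceiling]
    if ok.empty:
        raise ValueError("no grid complexity satisfies the rate ceiling")
    return float(ok["complexity"].min())
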