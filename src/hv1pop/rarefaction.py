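"""Rarefaction of haplotype richness by with-replacement resampling.

Populations of unequal size cannot be compared by their raw haplotype
counts, because richness grows with sample size.  Here each population is
repeatedly resampled *with replacement* at a common size ``g`` (multinomial
draws from the empirical haplotype frequencies), and the number of distinct
haplotypes per replicate is summarised as mean +/- sd over ``B`` replicates.

Because draws are with replacement, the exact expectation has the closed
form ``E[S_g] = sum_i [1 - (1 - p_i)^g]``, which serves as an analytic
oracle for the Monte-Carlo resampler.

Note that resampling a population at its own size generally *loses*
haplotypes (each replicate misses a random subset), so the rarefied mean of
the reference-size population sits below its observed richness; the result
carries an ``at_own_size`` flag marking that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .diversity import FrequencySpectrum


@dataclass(frozen=True)
class RarefactionResult:
    """Resampled haplotype richness at a fixed subsample size."""

    group_label: str
    g: int
    n_replicates: int
    mean_richness: float
    sd_richness: float
    seed: int
    at_own_size: bool = False
    replicate_counts: Optional[np.ndarray] = None


def expected_richness(spec: FrequencySpectrum, g: int) -> float:
    """Exact expected number of distinct haplotypes in ``g`` draws.

    With-replacement draws from the empirical frequencies ``p_i`` give
    ``E[S_g] = sum_i [1 - (1 - p_i)^g]``.
    """
    if g < 1:
        raise ValueError(f"subsample size must be >= 1, got {g}")
    return float(sum(1.0 - (1.0 - p) ** g for p in spec.frequencies().values()))


def resampled_richness(
    spec: FrequencySpectrum,
    g: int,
    n_replicates: int,
    seed: int,
    *,
    keep_replicates: bool = False,
) -> RarefactionResult:
    """Monte-Carlo rarefied haplotype richness.

    Each replicate draws ``g`` individuals independently with probabilities
    ``p_i = count_i / n`` (one multinomial draw) and counts the haplotypes
    hit at least once.  The sd is the population standard deviation over
    replicates (ddof=0).  Each replicate uses its own seed substream
    derived from ``(seed, replicate_index)``, so results do not depend on
    how replicates might be batched or parallelised.
    """
    if g < 1 or n_replicates < 1:
        raise ValueError("g and n_replicates must both be >= 1")
    probs = np.array(list(spec.frequencies().values()))
    counts = np.empty(n_replicates, dtype=np.int64)
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        draw = rng.multinomial(g, probs)
        counts[rep] = int(np.count_nonzero(draw))
    return RarefactionResult(
        group_label=spec.group_label,
        g=g,
        n_replicates=n_replicates,
        mean_richness=float(counts.mean()),
        sd_richness=float(counts.std(ddof=0)),
        seed=seed,
        at_own_size=(spec.n == g),
        replicate_counts=counts if keep_replicates else None,
    )
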