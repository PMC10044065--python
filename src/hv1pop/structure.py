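"""Population structure: pairwise Phi_ST and two-level AMOVA.

Analysis of molecular variance (AMOVA) partitions the total molecular
variance of a set of sequences into among- and within-population
components.  The sums of squared deviations are computed directly from the
pairwise distance matrix,

    SSD_total  = (1/N)   sum_{i<j} d_ij
    SSD_within = sum_p (1/n_p) sum_{i<j in p} d_ij

where d_ij is the squared molecular distance between individuals i and j.
With substitution-count distances the count itself serves as the squared
Euclidean surrogate (the convention of distance-matrix AMOVA for haplotype
data).  Variance components follow from the expected mean squares with
unequal sample sizes, Phi_ST = sigma2_a / (sigma2_a + sigma2_w), and the
significance of Phi_ST is assessed by permuting individuals among
populations.

Two distance modes are available: ``molecular`` (substitution counts,
Phi_ST, the default) and ``haplotype`` (0/1 identity distances, the
frequency-based F_ST analogue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .haplotyping import hamming_distance
from .sequence_io import WindowSequence


class StructureError(ValueError):
    """Invalid input to a structure analysis (population too small, etc.)."""


@dataclass(frozen=True)
class AmovaResult:
    """Outcome of a two-level AMOVA."""

    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    no_variation: bool = False


def distance_matrix(
    sequences: Sequence[WindowSequence | str],
    mode: str = "molecular",
) -> np.ndarray:
    """Pairwise distance matrix over sequences.

    ``molecular``: substitution counts with pairwise deletion;
    ``haplotype``: 0 if the sequences are identical over jointly determinate
    positions, else 1.
    """
    if mode not in ("molecular", "haplotype"):
        raise StructureError(f"unknown distance mode {mode!r}")
    n = len(sequences)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dist = hamming_distance(sequences[i], sequences[j])
            if mode == "haplotype":
                dist = 1 if dist > 0 else 0
            d[i, j] = d[j, i] = dist
    return d


def _amova_from_distances(
    d: np.ndarray, sizes: Sequence[int], order: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Return (ssd_among, ssd_within, sigma2_a, sigma2_w, phi) for one labelling.

    ``order`` lists individual indices population by population, with
    ``sizes`` giving the block lengths.
    """
    n_total = len(order)
    n_pops = len(sizes)
    ssd_total = d[np.ix_(order, order)].sum() / (2.0 * n_total)
    ssd_within = 0.0
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        ssd_within += d[np.ix_(idx, idx)].sum() / (2.0 * size)
        start += size
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = n_total - n_pops
    sigma2_w = ssd_within / df_within if df_within > 0 else 0.0
    # average sample size correction for unequal population sizes
    n_eff = (n_total - sum(s * s for s in sizes) / n_total) / df_among
    ms_among = ssd_among / df_among
    sigma2_a = (ms_among - sigma2_w) / n_eff
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0.0 else 0.0
    return ssd_among, ssd_within, sigma2_a, sigma2_w, phi


def amova_two_level(
    populations: Mapping[str, Sequence[WindowSequence | str]],
    *,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    mode: str = "molecular",
) -> AmovaResult:
    """Two-level AMOVA over two or more populations.

    The permutation p-value is the fraction of label permutations with
    Phi_ST at least as large as observed, with the +1/+1 correction
    ``p = (1 + #{Phi_perm >= Phi_obs}) / (1 + B)``.  A degenerate input with
    no molecular variation at all yields Phi_ST = 0 with ``no_variation``
    set.  Negative Phi_ST values are reported as computed.
    """
    if len(populations) < 2:
        raise StructureError("AMOVA requires at least two populations")
    sizes = []
    all_seqs: list[WindowSequence | str] = []
    for label, seqs in populations.items():
        if len(seqs) < 2:
            raise StructureError(
                f"population {label!r} has {len(seqs)} sequences; need >= 2"
            )
        sizes.append(len(seqs))
        all_seqs.extend(seqs)
    d = distance_matrix(all_seqs, mode=mode)
    n_total = len(all_seqs)
    identity = np.arange(n_total)

    if d.sum() == 0.0:
        return AmovaResult(
            ssd_among=0.0,
            ssd_within=0.0,
            df_among=len(sizes) - 1,
            df_within=n_total - len(sizes),
            sigma2_among=0.0,
            sigma2_within=0.0,
            pct_among=0.0,
            pct_within=0.0,
            phi_st=0.0,
            p_value=1.0,
            n_permutations=0,
            seed=seed,
            no_variation=True,
        )

    ssd_a, ssd_w, s2a, s2w, phi_obs = _amova_from_distances(d, sizes, identity)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        phi_perm = _amova_from_distances(d, sizes, perm)[4]
        if phi_perm >= phi_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations) if n_permutations > 0 else float("nan")

    total = s2a + s2w
    pct_a = 100.0 * s2a / total if total != 0 else 0.0
    return AmovaResult(
        ssd_among=ssd_a,
        ssd_within=ssd_w,
        df_among=len(sizes) - 1,
        df_within=n_total - len(sizes),
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=pct_a,
        pct_within=100.0 - pct_a if total != 0 else 0.0,
        phi_st=phi_obs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_phi_st(
    a: Sequence[WindowSequence | str],
    b: Sequence[WindowSequence | str],
    *,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    mode: str = "molecular",
) -> tuple[float, float]:
    """Phi_ST between two populations with a permutation p-value.

    Thin wrapper over :func:`amova_two_level` on the two populations; for a
    given seed the result is identical to the two-population AMOVA.
    """
    result = amova_two_level(
        {"a": list(a), "b": list(b)},
        n_permutations=n_permutations,
        seed=seed,
        mode=mode,
    )
    return result.phi_st, result.p_value


def pairwise_phi_st_matrix(
    populations: Mapping[str, Sequence[WindowSequence | str]],
    *,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    mode: str = "molecular",
) -> pd.DataFrame:
    """All pairwise Phi_ST values (lower triangle) with p-values (upper)."""
    labels = list(populations)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        out.loc[la, la] = 0.0
        for lb in labels[i + 1 :]:
            phi, p = pairwise_phi_st(
                populations[la],
                populations[lb],
                n_permutations=n_permutations,
                seed=seed,
                mode=mode,
            )
            out.loc[lb, la] = phi
            out.loc[la, lb] = p
    return out


def amova_table(result: AmovaResult) -> pd.DataFrame:
    """AMOVA result as the conventional source/df/SSD/variance table."""
    return pd.DataFrame(
        {
            "source": ["Among populations", "Within populations"],
            "df": [result.df_among, result.df_within],
            "SSD": [result.ssd_among, result.ssd_within],
            "variance_component": [result.sigma2_among, result.sigma2_within],
            "pct_variation": [result.pct_among, result.pct_within],
            "Phi_ST": [result.phi_st, np.nan],
            "p_value": [result.p_value, np.nan],
        }
    )
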