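"""Haplogroup frequency tables and molecular diversity estimators.

Three standard within-population statistics, in the conventions of Nei and
Tajima as implemented by the common population-genetics packages:

* haplotype (gene) diversity ``h = n/(n-1) * (1 - sum p_i^2)`` with Nei's
  sampling variance,
* mean number of pairwise differences ``k`` with Tajima's total variance
  (which includes the stochastic/coalescent component, not merely the
  sampling variance),
* nucleotide diversity ``pi = k / L_eff`` with the corresponding total
  variance per site.

Distances use pairwise deletion of missing positions (see
:func:`hv1pop.haplotyping.hamming_distance`).  ``L_eff`` is the effective
alignment length used to per-site-normalise ``k``; it defaults to the window
length but is configurable because published tables sometimes count an
extra indel column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .haplotyping import CallResult, hamming_distance
from .sequence_io import WindowSequence


class DiversityError(ValueError):
    """Invalid input to a diversity estimator (e.g. n < 2)."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencySpectrum:
    """Haplotype counts for one population."""

    counts: Mapping[str, int]
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.counts:
            raise DiversityError("empty frequency spectrum")
        if any(c < 1 for c in self.counts.values()):
            raise DiversityError("all haplotype counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {name: c / n for name, c in self.counts.items()}

    @classmethod
    def from_calls(cls, calls: Iterable[CallResult], group_label: str = "") -> "FrequencySpectrum":
        counts: dict[str, int] = {}
        for call in calls:
            counts[call.haplotype_name] = counts.get(call.haplotype_name, 0) + 1
        return cls(counts, group_label)


@dataclass(frozen=True)
class DiversitySummary:
    """Per-group diversity panel (counts plus the three estimators)."""

    group_label: str
    n: int
    n_haplotypes: int
    h: float
    h_sd: float
    k: float
    k_sd: float
    pi: float
    pi_sd: float
    l_eff: int


def haplotype_diversity(spec: FrequencySpectrum) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation.

    ``h = n/(n-1) * (1 - sum p_i^2)``;
    ``V(h) = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
    + sum p_i^2 - (sum p_i^2)^2 }``.
    """
    n = spec.n
    if n < 2:
        raise DiversityError(f"haplotype diversity requires n >= 2, got {n}")
    p = [c / n for c in spec.counts.values()]
    s2 = sum(x * x for x in p)
    s3 = sum(x ** 3 for x in p)
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 * s2) + s2 - s2 * s2)
    # rounding can push the variance of a monomorphic sample fractionally below 0
    return h, math.sqrt(max(var, 0.0))


def pairwise_difference_variance(k: float, n: int) -> float:
    """Tajima's total variance of the mean number of pairwise differences.

    The denominator ``11 (n^2 - 7n + 6) = 11 (n-1)(n-6)`` vanishes at n = 6
    and is negative below, so the formula only applies for n >= 7.
    """
    if n < 7:
        raise DiversityError("the total-variance formula requires n >= 7")
    return (3.0 * n * (n + 1) * k + 2.0 * (n * n + n + 3) * k * k) / (
        11.0 * (n * n - 7.0 * n + 6.0)
    )


def mean_pairwise_differences(
    windows: Sequence[WindowSequence | str],
) -> tuple[float, float]:
    """Mean pairwise substitution count ``k`` over all sequence pairs, with sd.

    The standard deviation is the square root of Tajima's total variance,
    which accounts for both the sampling and the evolutionary variance of
    ``k`` under neutrality.
    """
    n = len(windows)
    if n < 2:
        raise DiversityError(f"mean pairwise differences requires n >= 2, got {n}")
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hamming_distance(windows[i], windows[j])
    k = total / (n * (n - 1) / 2)
    sd = math.sqrt(pairwise_difference_variance(k, n)) if n >= 7 else float("nan")
    return k, sd


def mean_pairwise_differences_from_spectrum(
    spec: FrequencySpectrum,
    distances: Mapping[tuple[str, str], int],
) -> float:
    """``k`` from a haplotype spectrum plus a haplotype distance matrix.

    Equivalent to the sequence-by-sequence computation:
    ``k = sum_{i<j} c_i c_j d_ij / C(n, 2)`` (within-haplotype pairs
    contribute zero).  ``distances`` maps unordered name pairs to
    substitution counts.
    """
    n = spec.n
    if n < 2:
        raise DiversityError("requires n >= 2")
    names = list(spec.counts)
    total = 0.0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = distances.get((a, b), distances.get((b, a)))
            if d is None:
                raise DiversityError(f"missing distance for pair ({a}, {b})")
            total += spec.counts[a] * spec.counts[b] * d
    return total / (n * (n - 1) / 2)


def nucleotide_diversity_variance(pi: float, n: int, l_eff: int) -> float:
    """Tajima's total variance of nucleotide diversity.

    ``V(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2+n+3) pi^2 / (9 n (n-1))``.
    """
    if n < 2:
        raise DiversityError("requires n >= 2")
    if l_eff < 1:
        raise DiversityError("effective length must be >= 1")
    return (n + 1) * pi / (3.0 * (n - 1) * l_eff) + 2.0 * (
        n * n + n + 3
    ) * pi * pi / (9.0 * n * (n - 1))


def nucleotide_diversity(
    windows: Sequence[WindowSequence | str],
    l_eff: Optional[int] = None,
) -> tuple[float, float]:
    """Per-site nucleotide diversity ``pi = k / L_eff`` with its sd."""
    n = len(windows)
    if n < 2:
        raise DiversityError(f"nucleotide diversity requires n >= 2, got {n}")
    if l_eff is None:
        first = windows[0]
        l_eff = len(first.window_seq if isinstance(first, WindowSequence) else first)
    k, _ = mean_pairwise_differences(windows)
    pi = k / l_eff
    return pi, math.sqrt(nucleotide_diversity_variance(pi, n, l_eff))


def diversity_summary(
    group_label: str,
    calls: Sequence[CallResult],
    windows: Sequence[WindowSequence],
    l_eff: Optional[int] = None,
) -> DiversitySummary:
    """Assemble the full diversity panel for one population."""
    spec = FrequencySpectrum.from_calls(calls, group_label)
    h, h_sd = haplotype_diversity(spec)
    k, k_sd = mean_pairwise_differences(windows)
    if l_eff is None:
        l_eff = windows[0].length
    pi = k / l_eff
    pi_sd = math.sqrt(nucleotide_diversity_variance(pi, spec.n, l_eff))
    return DiversitySummary(
        group_label=group_label,
        n=spec.n,
        n_haplotypes=spec.n_haplotypes,
        h=h,
        h_sd=h_sd,
        k=k,
        k_sd=k_sd,
        pi=pi,
        pi_sd=pi_sd,
        l_eff=l_eff,
    )


def haplogroup_table(
    calls: Sequence[CallResult],
    grouping: Mapping[str, str],
    *,
    group_order: Optional[Sequence[str]] = None,
    total_label: str = "Total",
) -> pd.DataFrame:
    """Per-group haplogroup counts and percentages, with a Total row.

    For each group: sample count ``n``, per-haplogroup sequence counts with
    percentages (of the group total, rounded half-up to one decimal), the
    number of distinct haplotypes ``nHT``, and the number of haplotypes
    unique to the group (found in no other group).
    """
    missing = [c.sample_id for c in calls if c.sample_id not in grouping]
    if missing:
        raise DiversityError(
            f"samples missing from grouping: {', '.join(sorted(missing)[:10])}"
        )
    groups: dict[str, list[CallResult]] = {}
    for call in calls:
        groups.setdefault(grouping[call.sample_id], []).append(call)
    if group_order is None:
        group_order = sorted(groups)
    haplogroups = sorted({c.haplogroup for c in calls})

    haplotypes_by_group = {
        g: {c.haplotype_name for c in members} for g, members in groups.items()
    }

    rows = []
    for label in list(group_order) + [total_label]:
        if label == total_label:
            members = list(calls)
            others: set[str] = set()
            unique = sum(
                1
                for g in groups
                for ht in haplotypes_by_group[g]
                if all(ht not in haplotypes_by_group[o] for o in groups if o != g)
            )
        else:
            members = groups.get(label, [])
            unique = sum(
                1
                for ht in haplotypes_by_group.get(label, set())
                if all(ht not in haplotypes_by_group[o] for o in groups if o != label)
            )
        n = len(members)
        row: dict[str, object] = {"group": label, "n": n}
        for hg in haplogroups:
            count = sum(1 for c in members if c.haplogroup == hg)
            row[f"n_{hg}"] = count
            row[f"pct_{hg}"] = round_half_up(100.0 * count / n, 1) if n else 0.0
        row["nHT"] = len({c.haplotype_name for c in members})
        row["nUnique"] = unique
        rows.append(row)
    return pd.DataFrame(rows)


def write_diversity_report(
    summaries: Sequence[DiversitySummary],
    table: pd.DataFrame,
    path,
) -> None:
    """Write a combined group report: frequency table merged with diversity."""
    div = pd.DataFrame(
        {
            "group": [s.group_label for s in summaries],
            "h": [round(s.h, 4) for s in summaries],
            "h_sd": [round(s.h_sd, 4) for s in summaries],
            "pi": [round(s.pi, 6) for s in summaries],
            "pi_sd": [round(s.pi_sd, 6) for s in summaries],
            "k": [round(s.k, 6) for s in summaries],
            "k_sd": [round(s.k_sd, 6) for s in summaries],
            "L_eff": [s.l_eff for s in summaries],
        }
    )
    merged = table.merge(div, on="group", how="left")
    merged.to_csv(path, sep="\t", index=False)
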