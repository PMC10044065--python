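"""Synthetic reference windows, haplotype catalogs, and population samples.

The generator emulates the structure of a control-region haplotype survey:
a random reference window; a catalog of named haplotypes clustered into
haplogroups whose founders sit many substitutions apart while haplotypes
within a haplogroup differ by only a few; and population samples drawn
multinomially from per-population haplotype frequency spectra, optionally
perturbed by private novel mutations and N-masking.  Every sample's true
haplotype is recorded in a truth table, so the whole calling pipeline can
be validated end to end without any external data.

The default configuration mirrors a realistic village-dog survey: four
haplogroups (A, B, C, E) with overall weights ~0.54/0.23/0.15/0.08, and
three regional populations of sizes 318/44/55 whose spectra are skewed so
that the rare haplogroup is confined to the largest population and the
smallest-richness gradient runs across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .haplotyping import (
    HaplotypeCatalog,
    HaplotypeRecord,
    profile_from_window,
)
from .sequence_io import ReferenceWindow, SequenceRecord, write_fasta


class SimulationError(ValueError):
    """Inconsistent simulation configuration."""


#: overall haplogroup weights of the default survey-like configuration
DEFAULT_GROUP_WEIGHTS = {"A": 0.54, "B": 0.23, "C": 0.15, "E": 0.08}

#: per-population haplogroup weights of the default configuration
DEFAULT_POPULATION_WEIGHTS = {
    "SVN": {"A": 0.48, "B": 0.24, "C": 0.17, "E": 0.11},
    "CVN": {"A": 0.52, "B": 0.34, "C": 0.14, "E": 0.0},
    "NVN": {"A": 0.91, "B": 0.055, "C": 0.035, "E": 0.0},
}

DEFAULT_SAMPLE_SIZES = {"SVN": 318, "CVN": 44, "NVN": 55}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    ``between_group_distance`` must exceed twice
    ``within_group_max_distance`` so haplogroups stay separable by
    nearest-neighbour assignment.
    """

    L: int = 582
    window_start: int = 15458
    haplogroups: Sequence[str] = ("A", "B", "C", "E")
    haplotypes_per_group: int = 6
    between_group_distance: int = 12
    within_group_max_distance: int = 3
    population_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_POPULATION_WEIGHTS.items()}
    )
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES)
    )
    dirichlet_concentration: float = 0.8
    novel_mutation_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_group_distance <= 2 * self.within_group_max_distance:
            raise SimulationError(
                "between_group_distance must exceed twice "
                "within_group_max_distance to keep haplogroups separable"
            )
        for rate in (self.novel_mutation_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        needed = len(self.haplogroups) * (
            self.between_group_distance
            + (self.haplotypes_per_group - 1) * self.within_group_max_distance
        )
        if needed > self.L:
            raise SimulationError(
                f"window length {self.L} too short for "
                f"{len(self.haplogroups)} x {self.haplotypes_per_group} distinct haplotypes"
            )
        if set(self.sample_sizes) != set(self.population_weights):
            raise SimulationError("sample_sizes and population_weights must name the same populations")


_BASES = np.array(list("ACGT"))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_catalog(cfg: SimulationConfig) -> tuple[ReferenceWindow, HaplotypeCatalog]:
    """Generate a reference window and a haplotype catalog from a config.

    Haplogroup founders are placed ``between_group_distance`` substitutions
    from the reference at positions disjoint across founders; the remaining
    haplotypes of each group add 1..``within_group_max_distance``
    substitutions at fresh positions (star topology around the founder), so
    within-group distances never exceed twice the within-group bound and
    all window sequences are distinct.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    ref_seq = "".join(rng.choice(_BASES, size=cfg.L))
    ref = ReferenceWindow(ref_seq, start_pos=cfg.window_start, name="synthetic-reference")

    available = list(rng.permutation(cfg.L))  # 0-based offsets, used at most once
    catalog = HaplotypeCatalog(ref)
    for letter in cfg.haplogroups:
        founder = list(ref_seq)
        for _ in range(cfg.between_group_distance):
            off = available.pop()
            founder[off] = _other_base(rng, founder[off])
        founder_seq = "".join(founder)
        _add_record(catalog, f"{letter}1", letter, founder_seq, ref)
        for idx in range(2, cfg.haplotypes_per_group + 1):
            n_subs = int(rng.integers(1, cfg.within_group_max_distance + 1))
            child = list(founder_seq)
            for _ in range(n_subs):
                off = available.pop()
                child[off] = _other_base(rng, child[off])
            _add_record(catalog, f"{letter}{idx}", letter, "".join(child), ref)
    return ref, catalog


def _add_record(
    catalog: HaplotypeCatalog,
    name: str,
    haplogroup: str,
    seq: str,
    ref: ReferenceWindow,
) -> None:
    catalog.add(
        HaplotypeRecord(
            name=name,
            haplogroup=haplogroup,
            profile=profile_from_window(seq, ref),
            window_seq=seq,
            subhaplogroup=None,
            provenance="published",
        )
    )


def population_spectra(
    catalog: HaplotypeCatalog, cfg: SimulationConfig
) -> dict[str, dict[str, float]]:
    """Per-population haplotype probabilities.

    Haplogroup weights come from the config; within a haplogroup the
    probability mass is split by a Dirichlet draw (concentration
    ``dirichlet_concentration``), giving realistically skewed spectra.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    by_group: dict[str, list[str]] = {}
    for rec in catalog.records:
        by_group.setdefault(rec.haplogroup, []).append(rec.name)
    spectra: dict[str, dict[str, float]] = {}
    for pop, weights in cfg.population_weights.items():
        total = sum(weights.values())
        probs: dict[str, float] = {}
        for letter, weight in weights.items():
            if weight <= 0.0:
                continue
            names = by_group.get(letter)
            if not names:
                raise SimulationError(f"population {pop!r} weights unknown haplogroup {letter!r}")
            split = rng.dirichlet([cfg.dirichlet_concentration] * len(names))
            for name, share in zip(names, split):
                probs[name] = weight / total * float(share)
        spectra[pop] = probs
    return spectra


def simulate_samples(
    catalog: HaplotypeCatalog,
    cfg: SimulationConfig,
    spectra: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw population samples from the catalog.

    Returns the sampled sequence records (region set to the population
    label) and a truth table with columns sample_id, population,
    true_haplotype, has_novel_mutation, novel_position, n_masked.

    Novel mutations are private substitutions placed at positions at which
    no catalog haplotype is polymorphic; N-masking hits each base
    independently with ``missing_rate``.
    """
    if spectra is None:
        spectra = population_spectra(catalog, cfg)
    rng = np.random.default_rng([cfg.seed, 2])
    ref = catalog.reference
    polymorphic_offsets = {ref.offset(p) for p in catalog.polymorphic_positions()}
    clean_offsets = [o for o in range(cfg.L) if o not in polymorphic_offsets]

    records: list[SequenceRecord] = []
    truth_rows = []
    for pop in sorted(spectra):
        probs = spectra[pop]
        missing_names = set(probs) - {r.name for r in catalog.records}
        if missing_names:
            raise SimulationError(
                f"spectrum for {pop!r} names absent haplotypes {sorted(missing_names)}"
            )
        names = sorted(probs)
        p = np.array([probs[nm] for nm in names])
        p = p / p.sum()
        n = cfg.sample_sizes[pop]
        draws = rng.multinomial(n, p)
        individuals = [nm for nm, c in zip(names, draws) for _ in range(c)]
        rng.shuffle(individuals)
        for i, hap_name in enumerate(individuals):
            sample_id = f"{pop}_{i + 1:04d}"
            seq = list(catalog.get(hap_name).window_seq)
            novel_pos = None
            if cfg.novel_mutation_rate > 0 and rng.random() < cfg.novel_mutation_rate:
                off = clean_offsets[rng.integers(len(clean_offsets))]
                seq[off] = _other_base(rng, seq[off])
                novel_pos = ref.position(off)
            n_masked = 0
            if cfg.missing_rate > 0:
                mask = rng.random(cfg.L) < cfg.missing_rate
                for off in np.nonzero(mask)[0]:
                    seq[off] = "N"
                n_masked = int(mask.sum())
            records.append(SequenceRecord(sample_id, "".join(seq), region=pop))
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "population": pop,
                    "true_haplotype": hap_name,
                    "has_novel_mutation": novel_pos is not None,
                    "novel_position": novel_pos if novel_pos is not None else -1,
                    "n_masked": n_masked,
                }
            )
    return records, pd.DataFrame(truth_rows)


def write_simulation(
    outdir: str | Path,
    ref: ReferenceWindow,
    catalog: HaplotypeCatalog,
    records: Sequence[SequenceRecord],
    truth: pd.DataFrame,
) -> None:
    """Write the standard simulation bundle: FASTA, catalog, metadata, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reference.fasta", "w") as fh:
        fh.write(f">{ref.name} start={ref.start_pos}\n{ref.ref_seq}\n")
    catalog.to_tsv(outdir / "catalog.tsv")
    write_fasta(records, outdir / "samples.fasta")
    with open(outdir / "metadata.tsv", "w") as fh:
        fh.write("sample_id\tregion\tlocality\n")
        for rec in records:
            fh.write(f"{rec.sample_id}\t{rec.region or ''}\t{rec.locality or ''}\n")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
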