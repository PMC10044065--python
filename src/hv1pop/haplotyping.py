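"""Haplotype calling against a named catalog.

A catalog maps haplotype names (A9, B1, C2, E1, ...) to window sequences,
grouped into major haplogroups (the six mtDNA control-region clades A-F) and
optional sub-haplogroups (a1..a5, b1, b2, c2, ...).  Calling is exact
matching with wildcard semantics for missing data: a window matches a
catalog record when every determinate position agrees; N and ``-`` match
anything.  Windows matching no record are registered as novel haplotypes
named ``<haplogroup>n<k>`` (An1, An2, ..., Cn1, ...), with the haplogroup
taken from the nearest catalog record and truly new polymorphic sites
recorded.

Distances throughout are substitution counts with pairwise deletion:
positions carrying N or ``-`` in either sequence are skipped, and indels are
never counted as differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from .sequence_io import (
    DETERMINATE,
    ReferenceWindow,
    SequenceError,
    WindowSequence,
)


class CatalogError(ValueError):
    """Inconsistent or malformed haplotype catalog."""


class UncallableError(ValueError):
    """A window has too much missing data to register as a novel haplotype."""


class AmbiguousHaplogroupError(ValueError):
    """Nearest catalog neighbours at equal distance lie in different haplogroups."""


@dataclass(frozen=True)
class Substitution:
    """A single-base substitution at a 1-based mtDNA coordinate."""

    pos: int
    ref: str
    alt: str

    def token(self) -> str:
        return f"{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Indel:
    pos: int
    kind: str  # "ins" or "del"
    bases: str

    def token(self) -> str:
        return f"{self.pos}:{self.kind}:{self.bases}"


@dataclass(frozen=True)
class VariantProfile:
    """Differences of a haplotype relative to the reference window."""

    substitutions: tuple[Substitution, ...] = ()
    indels: tuple[Indel, ...] = ()

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise CatalogError("two substitutions share a position")

    def substituted_positions(self) -> set[int]:
        return {s.pos for s in self.substitutions}

    def token(self) -> str:
        subs = sorted(self.substitutions, key=lambda s: s.pos)
        inds = sorted(self.indels, key=lambda i: i.pos)
        return ";".join([s.token() for s in subs] + [i.token() for i in inds])

    @classmethod
    def parse(cls, text: str) -> "VariantProfile":
        """Parse semicolon-separated ``pos:ref>alt`` / ``pos:ins|del:bases`` tokens."""
        subs: list[Substitution] = []
        indels: list[Indel] = []
        text = text.strip()
        if not text or text == ".":
            return cls()
        for tok in text.split(";"):
            tok = tok.strip()
            if not tok:
                continue
            parts = tok.split(":")
            if len(parts) == 2 and ">" in parts[1]:
                ref, alt = parts[1].split(">")
                subs.append(Substitution(int(parts[0]), ref, alt))
            elif len(parts) == 3 and parts[1] in ("ins", "del"):
                indels.append(Indel(int(parts[0]), parts[1], parts[2]))
            else:
                raise CatalogError(f"cannot parse profile token {tok!r}")
        return cls(tuple(subs), tuple(indels))


def profile_from_window(win_seq: str, ref: ReferenceWindow) -> VariantProfile:
    """Derive a variant profile from a window sequence (N positions ignored)."""
    subs: list[Substitution] = []
    dels: list[Indel] = []
    for offset, (q, r) in enumerate(zip(win_seq, ref.ref_seq)):
        pos = ref.position(offset)
        if q == "-":
            dels.append(Indel(pos, "del", r))
        elif q in DETERMINATE and q != r:
            subs.append(Substitution(pos, r, q))
    return VariantProfile(tuple(subs), tuple(dels))


def window_from_profile(profile: VariantProfile, ref: ReferenceWindow) -> str:
    """Apply a variant profile to the reference, yielding the window sequence."""
    chars = list(ref.ref_seq)
    for sub in profile.substitutions:
        offset = ref.offset(sub.pos)
        if chars[offset] != sub.ref:
            raise CatalogError(
                f"profile ref base {sub.ref} at {sub.pos} does not match "
                f"reference base {chars[offset]}"
            )
        chars[offset] = sub.alt
    for indel in profile.indels:
        if indel.kind == "del":
            chars[ref.offset(indel.pos)] = "-"
        # insertions have no column in the fixed window frame
    return "".join(chars)


@dataclass
class HaplotypeRecord:
    """A named haplotype: variant profile plus derived window sequence."""

    name: str
    haplogroup: str
    profile: VariantProfile
    window_seq: str
    subhaplogroup: Optional[str] = None
    provenance: str = "published"  # or "novel"

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("haplotype name is empty")
        if self.name[0].upper() != self.haplogroup:
            raise CatalogError(
                f"haplotype {self.name!r}: name must start with its "
                f"haplogroup letter {self.haplogroup!r}"
            )


def hamming_distance(a: str | WindowSequence, b: str | WindowSequence) -> int:
    """Substitution count with pairwise deletion of missing positions.

    Counts positions where both sequences carry a determinate base (A/C/G/T)
    and the bases differ; positions with N or ``-`` in either sequence are
    skipped.  Sequences must have equal length.
    """
    sa = a.window_seq if isinstance(a, WindowSequence) else a
    sb = b.window_seq if isinstance(b, WindowSequence) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(
        1
        for x, y in zip(sa, sb)
        if x != y and x in DETERMINATE and y in DETERMINATE
    )


class CallResult(NamedTuple):
    """Outcome of calling one window sequence against a catalog."""

    sample_id: str
    haplotype_name: str
    haplogroup: str
    subhaplogroup: Optional[str]
    is_novel: bool
    distance_to_nearest_published: int
    novel_sites: frozenset[int]
    ambiguous: bool = False


class SubgroupCall(NamedTuple):
    label: Optional[str]
    ambiguous: bool


class HaplotypeCatalog:
    """A collection of named haplotypes sharing one reference window.

    The catalog enforces pairwise-distinct window sequences and tracks a
    per-haplogroup counter for naming novel haplotypes (An1, An2, ...).
    """

    def __init__(self, reference: ReferenceWindow, records: Iterable[HaplotypeRecord] = ()):
        self.reference = reference
        self.records: list[HaplotypeRecord] = []
        self._by_name: dict[str, HaplotypeRecord] = {}
        self._by_seq: dict[str, HaplotypeRecord] = {}
        self.novel_counter: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> HaplotypeRecord:
        return self._by_name[name]

    def add(self, rec: HaplotypeRecord) -> None:
        if rec.name in self._by_name:
            raise CatalogError(f"duplicate haplotype name {rec.name!r}")
        if len(rec.window_seq) != self.reference.length:
            raise CatalogError(
                f"haplotype {rec.name!r}: window length {len(rec.window_seq)} "
                f"!= reference length {self.reference.length}"
            )
        if rec.window_seq in self._by_seq:
            other = self._by_seq[rec.window_seq]
            raise CatalogError(
                f"haplotype {rec.name!r} duplicates the sequence of {other.name!r}"
            )
        self.records.append(rec)
        self._by_name[rec.name] = rec
        self._by_seq[rec.window_seq] = rec

    def polymorphic_positions(self) -> set[int]:
        """All 1-based positions at which any record carries a substitution."""
        out: set[int] = set()
        for rec in self.records:
            out |= rec.profile.substituted_positions()
        return out

    def next_novel_name(self, haplogroup: str) -> str:
        k = self.novel_counter.get(haplogroup, 0) + 1
        name = f"{haplogroup}n{k}"
        while name in self._by_name:  # user catalogs may already contain Xn names
            k += 1
            name = f"{haplogroup}n{k}"
        self.novel_counter[haplogroup] = k
        return name

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str | Path, reference: ReferenceWindow) -> "HaplotypeCatalog":
        """Load a catalog from TSV columns name, haplogroup, subhaplogroup, profile."""
        catalog = cls(reference)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {name: i for i, name in enumerate(header)}
            for required in ("name", "haplogroup", "profile"):
                if required not in cols:
                    raise CatalogError(f"catalog {path} lacks column {required!r}")
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                profile = VariantProfile.parse(fields[cols["profile"]])
                sub = None
                if "subhaplogroup" in cols and len(fields) > cols["subhaplogroup"]:
                    sub = fields[cols["subhaplogroup"]] or None
                    if sub == ".":
                        sub = None
                catalog.add(
                    HaplotypeRecord(
                        name=fields[cols["name"]],
                        haplogroup=fields[cols["haplogroup"]],
                        profile=profile,
                        window_seq=window_from_profile(profile, reference),
                        subhaplogroup=sub,
                    )
                )
        return catalog

    @classmethod
    def from_fasta(cls, path: str | Path, reference: ReferenceWindow) -> "HaplotypeCatalog":
        """Load a catalog from FASTA with ``name|haplogroup|subhaplogroup`` headers."""
        from Bio import SeqIO

        catalog = cls(reference)
        for entry in SeqIO.parse(str(path), "fasta"):
            parts = entry.id.split("|")
            name = parts[0]
            haplogroup = parts[1] if len(parts) > 1 and parts[1] else name[0].upper()
            sub = parts[2] if len(parts) > 2 and parts[2] else None
            seq = str(entry.seq).upper()
            catalog.add(
                HaplotypeRecord(
                    name=name,
                    haplogroup=haplogroup,
                    profile=profile_from_window(seq, reference),
                    window_seq=seq,
                    subhaplogroup=sub,
                )
            )
        return catalog

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\thaplogroup\tsubhaplogroup\tprofile\tprovenance\n")
            for rec in self.records:
                fh.write(
                    f"{rec.name}\t{rec.haplogroup}\t{rec.subhaplogroup or '.'}\t"
                    f"{rec.profile.token() or '.'}\t{rec.provenance}\n"
                )


def _wildcard_match(win_seq: str, cat_seq: str) -> bool:
    """True when every position determinate in both sequences agrees."""
    return hamming_distance(win_seq, cat_seq) == 0


def _nearest(win_seq: str, records: list[HaplotypeRecord]) -> tuple[int, list[HaplotypeRecord]]:
    best = None
    hits: list[HaplotypeRecord] = []
    for rec in records:
        d = hamming_distance(win_seq, rec.window_seq)
        if best is None or d < best:
            best, hits = d, [rec]
        elif d == best:
            hits.append(rec)
    assert best is not None
    return best, hits


def call_haplotype(
    win: WindowSequence,
    catalog: HaplotypeCatalog,
    *,
    register: bool = True,
    max_missing: float = 0.1,
) -> CallResult:
    """Call a window sequence against the catalog.

    Exact wildcard matching first (missing positions match anything); if
    several records match, the lexicographically smallest name wins and the
    call is flagged ambiguous.  Unmatched windows are registered as novel
    haplotypes unless ``register`` is false, in which case an
    :class:`UncallableError` is raised.
    """
    matches = [rec for rec in catalog.records if _wildcard_match(win.window_seq, rec.window_seq)]
    if matches:
        matches.sort(key=lambda r: r.name)
        rec = matches[0]
        return CallResult(
            sample_id=win.sample_id,
            haplotype_name=rec.name,
            haplogroup=rec.haplogroup,
            subhaplogroup=rec.subhaplogroup,
            is_novel=rec.provenance == "novel",
            distance_to_nearest_published=0 if rec.provenance == "published" else
            _nearest(win.window_seq, [r for r in catalog.records if r.provenance == "published"])[0]
            if any(r.provenance == "published" for r in catalog.records) else 0,
            novel_sites=frozenset(
                () if rec.provenance == "published" else _novel_sites_of(rec, catalog)
            ),
            ambiguous=len(matches) > 1,
        )
    if not register:
        raise UncallableError(f"{win.sample_id}: no catalog match")
    rec = register_novel(win, catalog, max_missing=max_missing)
    published = [r for r in catalog.records if r.provenance == "published"]
    dist = _nearest(win.window_seq, published)[0] if published else 0
    return CallResult(
        sample_id=win.sample_id,
        haplotype_name=rec.name,
        haplogroup=rec.haplogroup,
        subhaplogroup=rec.subhaplogroup,
        is_novel=True,
        distance_to_nearest_published=dist,
        novel_sites=frozenset(_novel_sites_of(rec, catalog)),
    )


def _novel_sites_of(rec: HaplotypeRecord, catalog: HaplotypeCatalog) -> set[int]:
    other_positions: set[int] = set()
    for other in catalog.records:
        if other.name != rec.name:
            other_positions |= other.profile.substituted_positions()
    return rec.profile.substituted_positions() - other_positions


def register_novel(
    win: WindowSequence,
    catalog: HaplotypeCatalog,
    *,
    max_missing: float = 0.1,
) -> HaplotypeRecord:
    """Register an unmatched window as a new named haplotype.

    The haplogroup is that of the nearest catalog record by Hamming
    distance; an equal-distance tie across different haplogroups is a hard
    error requiring manual assignment.  The new record's sequence is the
    reference with the window's determinate differences applied, so
    re-calling the same window returns the registered name.
    """
    if not catalog.records:
        raise CatalogError("cannot register a novel haplotype against an empty catalog")
    if win.missing_fraction() > max_missing:
        raise UncallableError(
            f"{win.sample_id}: uncallable, missing fraction "
            f"{win.missing_fraction():.2f} exceeds {max_missing:.2f}"
        )
    # idempotence: an identical (up to wildcards) window may already be registered
    for rec in catalog.records:
        if _wildcard_match(win.window_seq, rec.window_seq):
            return rec

    distance, nearest = _nearest(win.window_seq, catalog.records)
    haplogroups = {rec.haplogroup for rec in nearest}
    if len(haplogroups) > 1:
        raise AmbiguousHaplogroupError(
            f"{win.sample_id}: nearest neighbours at distance {distance} span "
            f"haplogroups {sorted(haplogroups)}; manual assignment required"
        )
    haplogroup = haplogroups.pop()
    profile = profile_from_window(win.window_seq, catalog.reference)
    record = HaplotypeRecord(
        name=catalog.next_novel_name(haplogroup),
        haplogroup=haplogroup,
        profile=profile,
        window_seq=window_from_profile(profile, catalog.reference),
        provenance="novel",
    )
    catalog.add(record)
    return record


def assign_subhaplogroup(
    rec: HaplotypeRecord,
    catalog: HaplotypeCatalog,
    *,
    max_sub_distance: int = 5,
) -> SubgroupCall:
    """Sub-haplogroup of the nearest annotated catalog record.

    Returns no label when no annotated record lies within
    ``max_sub_distance`` substitutions.  Equal-distance ties across distinct
    sub-haplogroups resolve to the lexicographically smallest label and are
    flagged ambiguous.
    """
    annotated = [r for r in catalog.records if r.subhaplogroup]
    if not annotated:
        return SubgroupCall(None, False)
    distance, nearest = _nearest(rec.window_seq, annotated)
    if distance > max_sub_distance:
        return SubgroupCall(None, False)
    labels = sorted({r.subhaplogroup for r in nearest})  # type: ignore[arg-type]
    return SubgroupCall(labels[0], len(labels) > 1)


def write_calls(calls: Iterable[CallResult], path: str | Path) -> None:
    """Write call results to TSV."""
    with open(path, "w") as fh:
        fh.write(
            "sample_id\thaplotype\thaplogroup\tsubhaplogroup\tis_novel\t"
            "distance\tnovel_sites\tambiguous\n"
        )
        for c in calls:
            sites = ",".join(str(p) for p in sorted(c.novel_sites)) or "."
            fh.write(
                f"{c.sample_id}\t{c.haplotype_name}\t{c.haplogroup}\t"
                f"{c.subhaplogroup or '.'}\t{int(c.is_novel)}\t"
                f"{c.distance_to_nearest_published}\t{sites}\t{int(c.ambiguous)}\n"
            )


def read_calls(path: str | Path) -> list[CallResult]:
    """Read back a call-result TSV written by :func:`write_calls`."""
    calls: list[CallResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sites = f[cols["novel_sites"]]
            calls.append(
                CallResult(
                    sample_id=f[cols["sample_id"]],
                    haplotype_name=f[cols["haplotype"]],
                    haplogroup=f[cols["haplogroup"]],
                    subhaplogroup=None if f[cols["subhaplogroup"]] == "." else f[cols["subhaplogroup"]],
                    is_novel=bool(int(f[cols["is_novel"]])),
                    distance_to_nearest_published=int(f[cols["distance"]]),
                    novel_sites=frozenset() if sites == "." else frozenset(int(p) for p in sites.split(",")),
                    ambiguous=bool(int(f[cols["ambiguous"]])),
                )
            )
    return calls
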