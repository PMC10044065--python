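"""FASTA input, the HV1 reference coordinate frame, and window projection.

The analysis operates on a fixed-length window of the mitochondrial control
region (hypervariable region 1).  Raw Sanger-derived sequences of varying
extent are projected into that window by global pairwise alignment against a
reference sequence, yielding equal-length ``WindowSequence`` objects that all
downstream modules consume.  Coordinates are 1-based positions in the
numbering of the reference mitochondrial genome; the window spans
``start_pos .. start_pos + L - 1`` (default 15458..16039 for the canonical
582-bp canine HV1 window).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

DETERMINATE = frozenset("ACGT")
#: characters accepted in raw input sequences (after uppercasing)
RAW_ALPHABET = frozenset("ACGTNU-")
#: characters a projected window sequence may contain
WINDOW_ALPHABET = frozenset("ACGTN-")

DEFAULT_WINDOW_START = 15458
DEFAULT_WINDOW_LENGTH = 582


class SequenceError(ValueError):
    """Malformed sequence input (bad characters, duplicate ids, empty file)."""


class ProjectionError(ValueError):
    """A raw sequence could not be projected into the reference window."""


@dataclass(frozen=True)
class ReferenceWindow:
    """The fixed coordinate frame all sequences are projected into.

    Parameters
    ----------
    ref_seq
        Reference sequence of the window, uppercase A/C/G/T only.
    start_pos
        1-based coordinate of the first window base in the numbering of the
        reference mitochondrial genome.
    name
        Label of the reference genome used for the numbering.
    """

    ref_seq: str
    start_pos: int = DEFAULT_WINDOW_START
    name: str = "reference-mtDNA"

    def __post_init__(self) -> None:
        if not self.ref_seq:
            raise SequenceError("reference window sequence is empty")
        bad = set(self.ref_seq) - DETERMINATE
        if bad:
            raise SequenceError(
                f"reference window may contain only A/C/G/T, found {sorted(bad)}"
            )
        if self.start_pos < 1:
            raise SequenceError("start_pos must be >= 1")

    @property
    def length(self) -> int:
        return len(self.ref_seq)

    @property
    def end_pos(self) -> int:
        """1-based coordinate of the last window base (inclusive)."""
        return self.start_pos + self.length - 1

    def offset(self, pos: int) -> int:
        """0-based window offset of a 1-based mtDNA coordinate."""
        if not (self.start_pos <= pos <= self.end_pos):
            raise ValueError(
                f"position {pos} outside window {self.start_pos}..{self.end_pos}"
            )
        return pos - self.start_pos

    def position(self, offset: int) -> int:
        """1-based mtDNA coordinate of a 0-based window offset."""
        if not (0 <= offset < self.length):
            raise ValueError(f"offset {offset} outside 0..{self.length - 1}")
        return self.start_pos + offset


@dataclass
class SequenceRecord:
    """A raw input sequence with optional sampling metadata."""

    sample_id: str
    raw_seq: str
    region: Optional[str] = None
    locality: Optional[str] = None


@dataclass
class WindowSequence:
    """A sequence projected into the reference window.

    ``window_seq`` has exactly the window length; ``N`` marks positions not
    covered by the raw read, ``-`` marks deletions relative to the reference.
    ``n_mismatches_to_ref`` counts positions where both the window and the
    reference carry a determinate base and they differ.
    """

    sample_id: str
    window_seq: str
    n_mismatches_to_ref: int = 0

    def __post_init__(self) -> None:
        bad = set(self.window_seq) - WINDOW_ALPHABET
        if bad:
            raise SequenceError(f"window sequence contains {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.window_seq)

    def missing_fraction(self) -> float:
        n_missing = sum(1 for c in self.window_seq if c not in DETERMINATE)
        return n_missing / len(self.window_seq)


def _normalise_seq(seq: str, sample_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in RAW_ALPHABET:
            raise SequenceError(
                f"record {sample_id!r}: invalid character {c!r} at position {i + 1}"
            )
    return seq


def _parse_header_tokens(description: str) -> tuple[str, Optional[str], Optional[str]]:
    tokens = description.split()
    sample_id = tokens[0]
    region = locality = None
    for tok in tokens[1:]:
        if tok.startswith("region="):
            region = tok.split("=", 1)[1] or None
        elif tok.startswith("locality="):
            locality = tok.split("=", 1)[1] or None
    return sample_id, region, locality


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The first whitespace-separated header token is the sample id; optional
    ``region=`` and ``locality=`` tokens are parsed from the remainder.
    Sequences are uppercased and U is normalised to T.  Duplicate sample ids,
    empty files, and characters outside A/C/G/T/N/U/- are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        sample_id, region, locality = _parse_header_tokens(entry.description)
        if sample_id in seen:
            raise SequenceError(f"duplicate sample id {sample_id!r} in {path}")
        seen.add(sample_id)
        seq = _normalise_seq(str(entry.seq), sample_id)
        if not seq:
            raise SequenceError(f"record {sample_id!r} has an empty sequence")
        records.append(SequenceRecord(sample_id, seq, region, locality))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, encoding region/locality as header tokens."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.sample_id
            if rec.region:
                header += f" region={rec.region}"
            if rec.locality:
                header += f" locality={rec.locality}"
            fh.write(f">{header}\n{rec.raw_seq}\n")


def read_metadata(path: str | Path) -> dict[str, tuple[Optional[str], Optional[str]]]:
    """Read a sample metadata TSV with columns sample_id, region, locality."""
    mapping: dict[str, tuple[Optional[str], Optional[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        if "sample_id" not in cols:
            raise SequenceError(f"metadata file {path} lacks a sample_id column")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sid = fields[cols["sample_id"]]
            region = fields[cols["region"]] if "region" in cols and len(fields) > cols["region"] else ""
            locality = fields[cols["locality"]] if "locality" in cols and len(fields) > cols["locality"] else ""
            mapping[sid] = (region or None, locality or None)
    return mapping


def apply_metadata(
    records: list[SequenceRecord],
    metadata: dict[str, tuple[Optional[str], Optional[str]]],
) -> None:
    """Override header-derived region/locality with a metadata table, in place."""
    for rec in records:
        if rec.sample_id in metadata:
            region, locality = metadata[rec.sample_id]
            rec.region = region
            rec.locality = locality


@functools.lru_cache(maxsize=8)
def _make_aligner() -> PairwiseAligner:
    # N scores 0 against everything so masked bases do not distort placement.
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 1.0 if a == b else -1.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    # free end gaps: flanking sequence outside the window is not penalised,
    # and short reads may cover only part of the window
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def project_to_window(
    record: SequenceRecord,
    ref: ReferenceWindow,
    *,
    min_coverage: float = 0.5,
    min_identity: float = 0.7,
) -> WindowSequence:
    """Project a raw sequence into the reference window by pairwise alignment.

    The raw sequence is globally aligned to the reference (match +1,
    mismatch -1, gap open -5, gap extend -1, end gaps free).  Alignment
    columns where the reference has a base are kept; insertions relative to
    the reference are dropped; deletions inside the covered span become
    ``-``; window positions beyond the read's aligned span become ``N``.

    Raises
    ------
    ProjectionError
        If fewer than ``min_coverage * L`` reference positions are covered
        ("insufficient overlap") or identity over covered determinate
        positions falls below ``min_identity`` ("unalignable").
    """
    query = record.raw_seq.replace("-", "")
    if len(query) < 0.5 * ref.length:
        raise ProjectionError(
            f"{record.sample_id}: insufficient overlap "
            f"(raw length {len(query)} < half the window length {ref.length})"
        )
    aligner = _make_aligner()
    alignment = aligner.align(ref.ref_seq, query)[0]
    t_row, q_row = alignment[0], alignment[1]

    first = last = None
    for i, c in enumerate(q_row):
        if c != "-":
            if first is None:
                first = i
            last = i
    assert first is not None and last is not None

    window_chars: list[str] = []
    n_match = n_mismatch = n_covered = 0
    for i, (tc, qc) in enumerate(zip(t_row, q_row)):
        if tc == "-":
            continue  # insertion in the query: column dropped
        if i < first or i > last:
            window_chars.append("N")
            continue
        n_covered += 1
        if qc == "-":
            window_chars.append("-")
        else:
            window_chars.append(qc)
            if qc in DETERMINATE and tc in DETERMINATE:
                if qc == tc:
                    n_match += 1
                else:
                    n_mismatch += 1

    if n_covered < min_coverage * ref.length:
        raise ProjectionError(
            f"{record.sample_id}: insufficient overlap "
            f"({n_covered} of {ref.length} reference positions covered)"
        )
    n_compared = n_match + n_mismatch
    if n_compared == 0 or n_match / n_compared < min_identity:
        raise ProjectionError(
            f"{record.sample_id}: unalignable "
            f"(identity {n_match}/{n_compared} over covered positions)"
        )
    window_seq = "".join(window_chars)
    assert len(window_seq) == ref.length
    return WindowSequence(record.sample_id, window_seq, n_mismatch)


def base_composition(windows: Iterable[WindowSequence]) -> dict[str, float]:
    """Fractions of A/C/G/T over all determinate bases of the given windows."""
    counts = {b: 0 for b in "ACGT"}
    for win in windows:
        for c in win.window_seq:
            if c in DETERMINATE:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise SequenceError("no determinate bases in input (all N/-)")
    return {b: counts[b] / total for b in "ACGT"}
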