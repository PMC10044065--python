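"""End-to-end orchestration: project, call, tabulate, estimate, export.

``run_pipeline`` wires the individual modules into one deterministic run:
sequences are projected into the reference window, called against the
catalog (novel haplotypes registered on the fly), and summarised as a
frequency/diversity report, a rare-haplogroup screen, a rarefaction table,
pairwise Phi_ST and AMOVA, and a haplotype network.  All randomness is
seeded and echoed into the run log; re-running an identical configuration
reproduces every output byte except the log's timestamp line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .diversity import (
    DiversityError,
    FrequencySpectrum,
    diversity_summary,
    haplogroup_table,
    round_half_up,
    write_diversity_report,
)
from .haplotyping import (
    CallResult,
    HaplotypeCatalog,
    call_haplotype,
    write_calls,
)
from .network import build_msn, export_network, write_node_table
from .rarefaction import resampled_richness
from .sequence_io import (
    ReferenceWindow,
    SequenceRecord,
    WindowSequence,
    apply_metadata,
    project_to_window,
    read_fasta,
    read_metadata,
)
from .structure import amova_table, amova_two_level, pairwise_phi_st_matrix

#: group label applied to samples lacking region metadata
OTHER_LABEL = "Other"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and samples."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    fasta: Path
    catalog: Path
    reference: Path
    outdir: Path
    metadata: Optional[Path] = None
    window_start: int = 15458
    l_eff: Optional[int] = None  # default: the window length
    rarefaction_size: int = 44
    rarefaction_replicates: int = 1000
    seed: int = 1
    n_permutations: int = 10_000
    epsilon: int = 0
    rare_haplogroup: str = "E"
    distance_mode: str = "molecular"


def load_reference(path: str | Path, window_start: int = 15458) -> ReferenceWindow:
    """Load the reference window from a single-record FASTA.

    A ``start=<pos>`` token in the header overrides ``window_start``.
    """
    records = read_fasta(path)
    rec = records[0]
    start = window_start
    # re-read the raw header for a start= token
    with open(path) as fh:
        header = fh.readline().strip().lstrip(">")
    for tok in header.split():
        if tok.startswith("start="):
            start = int(tok.split("=", 1)[1])
    return ReferenceWindow(rec.raw_seq, start_pos=start, name=rec.sample_id)


def call_all(
    records: Sequence[SequenceRecord],
    catalog: HaplotypeCatalog,
) -> tuple[list[WindowSequence], list[CallResult]]:
    """Project and call every record; novel haplotypes are registered."""
    windows: list[WindowSequence] = []
    calls: list[CallResult] = []
    failures: list[str] = []
    for rec in records:
        try:
            win = project_to_window(rec, catalog.reference)
            calls.append(call_haplotype(win, catalog))
            windows.append(win)
        except ValueError as exc:
            failures.append(f"{rec.sample_id}: {exc}")
    if failures:
        raise PipelineError(
            "calling failed for "
            f"{len(failures)} sample(s): " + "; ".join(failures[:5])
        )
    return windows, calls


def rare_haplogroup_report(
    calls: Sequence[CallResult],
    grouping: Mapping[str, str],
    target_haplogroup: str,
    *,
    group_order: Optional[Sequence[str]] = None,
    total_label: str = "Total",
) -> pd.DataFrame:
    """Screen for a rare haplogroup: per group, carriers and distinct haplotypes.

    Columns: group, n, n_haplotypes (distinct haplotypes of the target
    haplogroup present in the group), n_individuals (carriers), pct
    (carriers as a percentage of the group, one decimal).
    """
    if not calls:
        raise DiversityError("no calls given")
    known = {c.haplogroup for c in calls}
    if target_haplogroup not in "ABCDEF":
        raise DiversityError(
            f"unknown haplogroup {target_haplogroup!r}; expected one of A..F"
        )
    groups: dict[str, list[CallResult]] = {}
    for call in calls:
        label = grouping.get(call.sample_id, OTHER_LABEL)
        groups.setdefault(label, []).append(call)
    if group_order is None:
        group_order = sorted(groups)
    rows = []
    for label in list(group_order) + [total_label]:
        members = list(calls) if label == total_label else groups.get(label, [])
        carriers = [c for c in members if c.haplogroup == target_haplogroup]
        n = len(members)
        rows.append(
            {
                "group": label,
                "n": n,
                "n_haplotypes": len({c.haplotype_name for c in carriers}),
                "n_individuals": len(carriers),
                "pct": round_half_up(100.0 * len(carriers) / n, 1) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a mapping from artifact name to written path.  Artifacts:
    calls, group_report, rare_haplogroup_report, rarefaction, phi_st_matrix,
    amova, network edges/nodes (+ dot, graphml), catalog (including any
    novel haplotypes registered during calling), and the run log.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"hv1pop {__version__}",
        f"timestamp: {datetime.now(timezone.utc).isoformat()}",
        f"config: {cfg}",
    ]

    ref = load_reference(cfg.reference, cfg.window_start)
    catalog = HaplotypeCatalog.from_tsv(cfg.catalog, ref)
    n_published = len(catalog)
    records = read_fasta(cfg.fasta)
    if cfg.metadata:
        apply_metadata(records, read_metadata(cfg.metadata))

    windows, calls = call_all(records, catalog)
    win_by_id = {w.sample_id: w for w in windows}
    grouping = {rec.sample_id: rec.region or OTHER_LABEL for rec in records}
    region_labels = [
        label
        for label in dict.fromkeys(grouping.values())  # insertion order
        if label != OTHER_LABEL
    ]
    group_order = region_labels + ([OTHER_LABEL] if OTHER_LABEL in grouping.values() else [])

    artifacts: dict[str, Path] = {}

    def _register(name: str, path: Path) -> Path:
        artifacts[name] = path
        log_lines.append(f"wrote {name}: {path.name}")
        return path

    write_calls(calls, _register("calls", outdir / "calls.tsv"))
    catalog.to_tsv(_register("catalog", outdir / "catalog_with_novel.tsv"))
    log_lines.append(
        f"called {len(calls)} samples; catalog grew from {n_published} to "
        f"{len(catalog)} haplotypes"
    )

    # Table-1-style report: frequency table + per-group diversity.
    table = haplogroup_table(calls, grouping, group_order=group_order)
    l_eff = cfg.l_eff or ref.length
    summaries = []
    calls_by_group: dict[str, list[CallResult]] = {}
    for call in calls:
        calls_by_group.setdefault(grouping[call.sample_id], []).append(call)
    for label in region_labels:
        members = calls_by_group.get(label, [])
        if len(members) >= 4:
            wins = [win_by_id[c.sample_id] for c in members]
            summaries.append(diversity_summary(label, members, wins, l_eff))
    if len(calls) >= 4:  # Total row spans all samples, Other included
        summaries.append(diversity_summary("Total", list(calls), windows, l_eff))
    write_diversity_report(
        summaries, table, _register("group_report", outdir / "group_report.tsv")
    )

    rare = rare_haplogroup_report(
        calls, grouping, cfg.rare_haplogroup, group_order=group_order
    )
    rare.to_csv(
        _register("rare_haplogroup_report", outdir / "rare_haplogroup_report.tsv"),
        sep="\t",
        index=False,
    )

    # rarefaction per region at the common size
    rows = []
    for label in region_labels:
        members = calls_by_group.get(label, [])
        if not members:
            continue
        spec = FrequencySpectrum.from_calls(members, label)
        res = resampled_richness(
            spec, cfg.rarefaction_size, cfg.rarefaction_replicates, cfg.seed
        )
        rows.append(
            {
                "group": label,
                "n": spec.n,
                "nHT": spec.n_haplotypes,
                "g": res.g,
                "replicates": res.n_replicates,
                "mean_richness": round(res.mean_richness, 2),
                "sd_richness": round(res.sd_richness, 2),
                "at_own_size": int(res.at_own_size),
            }
        )
    pd.DataFrame(rows).to_csv(
        _register("rarefaction", outdir / "rarefaction.tsv"), sep="\t", index=False
    )

    # structure: populations = regions with at least two samples
    populations = {
        label: [win_by_id[c.sample_id] for c in calls_by_group[label]]
        for label in region_labels
        if len(calls_by_group.get(label, [])) >= 2
    }
    if len(populations) >= 2:
        matrix = pairwise_phi_st_matrix(
            populations,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            mode=cfg.distance_mode,
        )
        matrix.to_csv(_register("phi_st_matrix", outdir / "phi_st_matrix.tsv"), sep="\t")
        amova = amova_two_level(
            populations,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            mode=cfg.distance_mode,
        )
        amova_table(amova).to_csv(
            _register("amova", outdir / "amova.tsv"), sep="\t", index=False
        )

    # haplotype network over all called haplotypes
    observed = {c.haplotype_name for c in calls}
    counts: dict[str, int] = {}
    group_counts: dict[str, dict[str, int]] = {g: {} for g in group_order}
    for call in calls:
        counts[call.haplotype_name] = counts.get(call.haplotype_name, 0) + 1
        g = grouping[call.sample_id]
        group_counts[g][call.haplotype_name] = group_counts[g].get(call.haplotype_name, 0) + 1
    haplotypes = [catalog.get(name) for name in sorted(observed)]
    if len(haplotypes) >= 2:
        net = build_msn(
            haplotypes, cfg.epsilon, counts=counts, group_counts=group_counts
        )
        export_network(net, _register("network_edges", outdir / "network_edges.tsv"), "edge_tsv")
        export_network(net, _register("network_dot", outdir / "network.dot"), "dot")
        export_network(net, _register("network_graphml", outdir / "network.graphml"), "graphml")
        write_node_table(net, _register("network_nodes", outdir / "network_nodes.tsv"))

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = log_path
    return artifacts
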