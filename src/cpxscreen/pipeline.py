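"""End-to-end orchestration: matrix build -> scan -> annotate -> classify -> call.

``run_pipeline`` executes the whole screen from a :class:`RunConfig`,
writing every intermediate artifact (matrix TSVs, hit BED/TSV, candidate
tables, a JSON summary) so each stage is resumable from files via the CLI
subcommands.  Defaults mirror the published screen's constants: pseudocount
0.5, promoter window -700/+100 around the start codon, threshold
mean - SD over all scoreable windows, two-fold regulation rule, and a
high-score review flag at 17.68 bits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .motif import (
    BackgroundModel,
    build_matrix_from_sites,
    expand_collection,
    read_sites,
    write_matrix,
)
from .promoters import (
    build_clusters,
    build_promoter_windows,
    classify,
    read_genes_genbank,
    read_genes_gff3,
    write_boxes_bed,
    write_candidates_tsv,
)
from .regulation import (
    DEFAULT_GROUPS,
    FoldChangeTable,
    call_regulation,
    count_regulated,
    count_union,
    write_calls_tsv,
)
from .scan import (
    ScanHit,
    read_genome,
    scan_genome,
    write_hits_bed,
    write_hits_tsv,
)

HIGH_SCORE_FLAG = 17.68  # bits; sites above this always mapped to a regulated gene


@dataclass
class RunConfig:
    """Serializable configuration; defaults match the screen's stated values."""

    sites: str = ""
    genome: str = ""
    genes: str = ""
    fold_changes: str = ""
    outdir: str = "cpxscreen_out"
    pseudocount: float = 0.5
    background: str = "uniform"  # or "genomic"
    pseudocount_allocation: str = "uniform"  # or "background"
    strands: str = "+-"
    circular: bool = False
    threshold_mode: str = "adaptive"  # "adaptive" (mean - SD) or "fixed"
    fixed_threshold: float = 0.0  # bits; used when threshold_mode == "fixed"
    threshold_population: str = "genome"  # or "promoter"
    upstream: int = 700
    downstream: int = 100
    cluster_max_gap: int = 50
    fold_threshold: float = 2.0
    high_score_flag: float = HIGH_SCORE_FLAG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strands not in ("+", "-", "+-"):
            raise ValueError("strands must be '+', '-' or '+-'")
        if self.background not in ("uniform", "genomic"):
            raise ValueError("background must be 'uniform' or 'genomic'")
        if self.threshold_population not in ("genome", "promoter"):
            raise ValueError("threshold_population must be 'genome' or 'promoter'")
        if self.threshold_mode not in ("adaptive", "fixed"):
            raise ValueError("threshold_mode must be 'adaptive' or 'fixed'")

    @property
    def strand_tuple(self) -> tuple[str, ...]:
        return tuple(self.strands)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunSummary:
    """Per-stage counts and parameters of one pipeline run."""

    version: str
    config: dict
    n_sites: int
    scans: dict  # per matrix length: mean/sd/threshold/n_windows/n_hits/...
    n_candidates: int
    group_counts: dict
    n_high_score_hits: int
    regulation: dict | None
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def export_tracks(results: Sequence, candidates, outdir: str | Path) -> dict[str, Path]:
    """Write one BED per matrix length, the candidate best-box BED, and the
    candidate TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for result in results:
        tag = f"hits_{result.matrix_length}bp"
        bed = outdir / f"{tag}.bed"
        tsv = outdir / f"{tag}.tsv"
        max_score = max((h.score for h in result.hits), default=1.0)
        write_hits_bed(result.hits, bed, max_score)
        write_hits_tsv(result.hits, tsv)
        paths[tag] = bed
        paths[tag + "_tsv"] = tsv
    cand_tsv = outdir / "candidates.tsv"
    cand_bed = outdir / "candidate_boxes.bed"
    write_candidates_tsv(candidates, cand_tsv)
    write_boxes_bed(candidates, cand_bed)
    paths["candidates"] = cand_tsv
    paths["candidate_boxes"] = cand_bed
    return paths


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full screen and write all artifacts under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites15 = read_sites(config.sites)
    if sites15.site_length != 15:
        raise ValueError("the training-site file must contain 15-bp sites")
    sites16 = expand_collection(sites15)

    genomes = read_genome(config.genome, circular=config.circular)
    if config.background == "genomic":
        background = BackgroundModel.from_sequence(
            "".join(g.sequence for g in genomes))
    else:
        background = BackgroundModel()

    matrices = {}
    for label, sites in (("15", sites15), ("16", sites16)):
        matrix = build_matrix_from_sites(
            sites, config.pseudocount, background=background,
            allocation=config.pseudocount_allocation)
        write_matrix(matrix, outdir / f"pssm_{label}bp.tsv",
                     pseudocount=config.pseudocount)
        matrices[label] = matrix

    genes_path = Path(config.genes)
    if genes_path.suffix.lower() in {".gb", ".gbk", ".genbank"}:
        genes = read_genes_genbank(genes_path)
    else:
        genes = read_genes_gff3(genes_path)
    contig_lengths = {g.contig_id: len(g) for g in genomes}
    windows = build_promoter_windows(genes, contig_lengths,
                                     config.upstream, config.downstream)

    results = []
    all_hits: list[ScanHit] = []
    scan_summaries = {}
    fixed = config.fixed_threshold if config.threshold_mode == "fixed" else None
    for label, matrix in matrices.items():
        if config.threshold_population == "promoter" and fixed is None:
            result = _scan_promoter_population(matrix, genomes, windows,
                                               config.strand_tuple)
        else:
            result = scan_genome(matrix, genomes, config.strand_tuple, fixed)
        results.append(result)
        all_hits.extend(result.hits)
        scan_summaries[label] = result.summary()

    assignments = {}
    from .promoters import assign_hits

    assignments = assign_hits(all_hits, windows)
    clusters = build_clusters(genes, config.cluster_max_gap)
    candidates = classify(assignments, genes, clusters,
                          config.cluster_max_gap, windows)
    export_tracks(results, candidates, outdir)

    group_counts: dict[str, int] = {g: 0 for g in "ABCD"}
    for c in candidates:
        group_counts[c.group] += 1

    high = [h for h in all_hits if h.score > config.high_score_flag]
    with (outdir / "high_score_hits.tsv").open("w") as fh:
        fh.write("contig\tstart0\tend0\tstrand\tlength\tscore_bits\tsequence\n")
        for h in sorted(high, key=lambda h: -h.score):
            fh.write(f"{h.contig_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                     f"{h.length}\t{h.score:.6g}\t{h.sequence}\n")

    regulation_summary = None
    if config.fold_changes:
        table = FoldChangeTable.read_tsv(config.fold_changes)
        calls = call_regulation(table, config.fold_threshold)
        write_calls_tsv(calls, outdir / "regulation_calls.tsv")
        regulation_summary = {
            "n_genes": len(table.folds),
            "regulated_per_group": {
                g: count_regulated(table, g, config.fold_threshold)
                for g in table.groups
            },
            "regulated_union": count_union(table, config.fold_threshold),
        }

    summary = RunSummary(
        version=__version__,
        config=dataclasses.asdict(config),
        n_sites=len(sites15),
        scans=scan_summaries,
        n_candidates=len(candidates),
        group_counts=group_counts,
        n_high_score_hits=len(high),
        regulation=regulation_summary,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    summary.to_json(outdir / "run_summary.json")
    config.to_yaml(outdir / "config_echo.yaml")
    return summary


def _scan_promoter_population(matrix, genomes, windows, strands):
    """Scan whole contigs but calibrate the threshold on promoter windows only."""
    from .scan import ScanResult, _scored_windows, calibrate_threshold, filter_hits

    window_spans: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        window_spans.setdefault(w.contig_id, []).append((w.start, w.end))
    population: list[float] = []
    per_contig = []
    n_skipped = 0
    for genome in genomes:
        records, skipped = _scored_windows(matrix, genome, strands)
        n_skipped += skipped
        per_contig.append((genome, records))
        spans = window_spans.get(genome.contig_id, [])
        for start, _, score in records:
            end = start + matrix.length
            if any(a <= start and end <= b for a, b in spans):
                population.append(score)
    mu, sigma, tau = calibrate_threshold(population)
    hits = []
    for genome, records in per_contig:
        hits.extend(filter_hits(records, tau, genome, matrix.length))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return ScanResult(hits, mu, sigma, tau, len(population), n_skipped,
                      matrix.length)
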