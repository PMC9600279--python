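"""Convention sweep for the genome-scale screen.

The printed site counts of a published screen depend on conventions its
methods text does not pin down: which strands are scanned, the background
base distribution, how the pseudocount is allocated, whether the threshold
population is the whole genome or only promoter windows, and whether
overlapping hits are deduplicated to loci.  This module runs the screen
under every combination of those conventions on user-supplied inputs (a
genome FASTA/GenBank and the curated binding-site set) and tabulates the
15-bp and 16-bp hit counts per combination, so the convention set matching
an external reference can be identified empirically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .motif import (
    BackgroundModel,
    BindingSiteCollection,
    build_matrix_from_sites,
    expand_collection,
    read_sites,
)
from .scan import GenomeSequence, read_genome, scan_genome


@dataclass(frozen=True)
class Convention:
    strands: tuple[str, ...]  # ("+",) or ("+", "-")
    background: str  # "uniform" or "genomic"
    allocation: str  # "uniform" or "background"
    dedup: bool  # collapse overlapping same-length hits to loci


def _dedup_count(hits) -> int:
    count = 0
    prev_end = -1
    for h in sorted(hits, key=lambda h: (h.contig_id, h.start)):
        if h.start >= prev_end:
            count += 1
            prev_end = h.end
        else:
            prev_end = max(prev_end, h.end)
    return count


def convention_sweep(
    sites15: BindingSiteCollection,
    genomes: Sequence[GenomeSequence],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Hit counts of the 15-bp and 16-bp screens per convention combination."""
    if sites15.site_length != 15:
        raise ValueError("the curated training set must be 15 bp")
    sites16 = expand_collection(sites15)
    genome_bg = BackgroundModel.from_sequence(
        "".join(g.sequence for g in genomes))
    rows = []
    for strands, bg_mode, allocation, dedup in itertools.product(
            [("+",), ("+", "-")], ["uniform", "genomic"],
            ["uniform", "background"], [False, True]):
        background = BackgroundModel() if bg_mode == "uniform" else genome_bg
        counts = {}
        for label, sites in (("15", sites15), ("16", sites16)):
            matrix = build_matrix_from_sites(
                sites, pseudocount, background=background, allocation=allocation)
            result = scan_genome(matrix, list(genomes), strands)
            counts[label] = (_dedup_count(result.hits) if dedup
                             else len(result.hits))
            counts[f"threshold_{label}"] = result.threshold
        rows.append({
            "strands": "".join(strands),
            "background": bg_mode,
            "pseudocount_allocation": allocation,
            "dedup_loci": dedup,
            "n_hits_15": counts["15"],
            "n_hits_16": counts["16"],
            "threshold_15": counts["threshold_15"],
            "threshold_16": counts["threshold_16"],
        })
    return pd.DataFrame(rows)


def convention_sweep_files(sites_path: str | Path, genome_path: str | Path,
                           pseudocount: float = 0.5) -> pd.DataFrame:
    """Run :func:`convention_sweep` on a sites file and a genome file."""
    return convention_sweep(read_sites(sites_path), read_genome(genome_path),
                            pseudocount)
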