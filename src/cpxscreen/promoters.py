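"""Promoter windows, hit-to-gene assignment, and the four location groups.

Candidate CpxR-regulated genes are screened in a strand-aware promoter
window spanning 700 bp upstream through 100 bp downstream of the start
codon.  A scan hit belongs to a gene when its interval is fully contained
in the gene's window; a hit between divergently transcribed genes may
belong to both.  Candidates are then classified by box layout:

* **A** — boxes distributed over a multi-gene cluster (operon-like run of
  same-strand genes with short intergenic gaps) with two or more distinct
  boxes in total,
* **B** — two or more distinct boxes in a single gene's window,
* **C** — a single box shared through an intergenic region by a divergent
  gene pair (inside both windows),
* **D** — a single box in a single gene's window.

Priority A > B > C > D resolves genes matching several descriptions.
Distinct boxes are non-overlapping hit loci; overlapping 15/16-bp hits at
one locus collapse to the highest-scoring one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .scan import ScanHit

DEFAULT_UPSTREAM = 700
DEFAULT_DOWNSTREAM = 100
DEFAULT_MAX_GAP = 50


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its start codon.

    ``start_codon`` is the 0-based forward-strand coordinate of the first
    base of the start codon: the leftmost CDS base for a plus-strand gene,
    the rightmost for a minus-strand gene.
    """

    gene_id: str
    contig_id: str
    strand: str
    start_codon: int
    end: int | None = None  # forward-strand coordinate of the far CDS end (exclusive)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start_codon < 0:
            raise ValueError("start codon coordinate must be non-negative")

    @property
    def extent(self) -> tuple[int, int]:
        """Forward-strand [left, right) span of the CDS (point if end unknown)."""
        if self.end is None:
            return self.start_codon, self.start_codon + 1
        lo, hi = sorted((self.start_codon, self.end))
        return lo, max(hi, lo + 1)


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter interval [start, end) on the forward strand."""

    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    clipped: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, hit: ScanHit) -> bool:
        return (hit.contig_id == self.contig_id
                and self.start <= hit.start and hit.end <= self.end)


@dataclass(frozen=True)
class GeneCluster:
    """Consecutive same-strand genes with short intergenic gaps."""

    gene_ids: tuple[str, ...]
    contig_id: str
    strand: str

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class CandidateAssignment:
    """A candidate gene, its distinct boxes, and its location group."""

    gene_id: str
    boxes: list[ScanHit]
    group: str
    best_box: ScanHit
    shared_with: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "C" and self.shared_with is None:
            raise ValueError("group C requires a divergent partner gene")
        if not self.boxes:
            raise ValueError("a candidate must have at least one box")


def build_promoter_windows(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[PromoterWindow]:
    """One window per gene: ``upstream`` bp before through ``downstream`` bp
    after the start codon (the start-codon base counts as downstream base 1),
    mirrored for minus-strand genes and clipped to the contig."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window bounds must be non-negative")
    windows = []
    for gene in genes:
        length = contig_lengths[gene.contig_id]
        if not 0 <= gene.start_codon < length:
            raise ValueError(
                f"start codon of {gene.gene_id!r} at {gene.start_codon} is "
                f"outside contig {gene.contig_id!r} (length {length})"
            )
        if gene.strand == "+":
            a, b = gene.start_codon - upstream, gene.start_codon + downstream
        else:
            a, b = gene.start_codon - downstream + 1, gene.start_codon + upstream + 1
        ca, cb = max(a, 0), min(b, length)
        windows.append(PromoterWindow(
            gene.gene_id, gene.contig_id, gene.strand, ca, cb,
            clipped=(ca != a or cb != b),
        ))
    return windows


def assign_hits(
    hits: Sequence[ScanHit],
    windows: Sequence[PromoterWindow],
) -> dict[str, list[ScanHit]]:
    """Map each hit to every gene whose window fully contains it."""
    trees: dict[str, IntervalTree] = {}
    by_id = {}
    for w in windows:
        if w.end > w.start:
            trees.setdefault(w.contig_id, IntervalTree()).addi(w.start, w.end, w)
        by_id[w.gene_id] = w
    assigned: dict[str, list[ScanHit]] = {}
    for hit in hits:
        tree = trees.get(hit.contig_id)
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            w: PromoterWindow = iv.data
            if w.contains(hit):
                assigned.setdefault(w.gene_id, []).append(hit)
    for gene_hits in assigned.values():
        gene_hits.sort(key=lambda h: (h.start, h.strand, h.length))
    return assigned


def build_clusters(genes: Sequence[GeneModel], max_gap: int = DEFAULT_MAX_GAP
                   ) -> list[GeneCluster]:
    """Maximal runs of same-strand neighbours with intergenic gap <= max_gap."""
    clusters: list[GeneCluster] = []
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.extent[0]))
    run: list[GeneModel] = []

    def flush() -> None:
        if run:
            clusters.append(GeneCluster(tuple(g.gene_id for g in run),
                                        run[0].contig_id, run[0].strand))

    for gene in ordered:
        if (run and gene.contig_id == run[-1].contig_id
                and gene.strand == run[-1].strand
                and gene.extent[0] - run[-1].extent[1] <= max_gap):
            run.append(gene)
        else:
            flush()
            run = [gene]
    flush()
    return clusters


def distinct_boxes(hits: Iterable[ScanHit]) -> list[ScanHit]:
    """Collapse overlapping hits at one locus, keeping the highest score.

    Ties on score break toward the earlier, shorter hit so the result is
    deterministic regardless of input order.
    """
    ordered = sorted(hits, key=lambda h: (h.contig_id, h.start, h.end))
    groups: list[list[ScanHit]] = []
    for hit in ordered:
        if groups and any(hit.overlaps(g) for g in groups[-1]):
            groups[-1].append(hit)
        else:
            groups.append([hit])
    return [max(g, key=lambda h: (h.score, -h.start, -h.length)) for g in groups]


def rank_boxes(boxes: Sequence[ScanHit]) -> list[ScanHit]:
    """Sort by score descending; ties by genomic coordinate ascending."""
    if not boxes:
        raise ValueError("rank_boxes needs at least one box")
    return sorted(boxes, key=lambda h: (-h.score, h.contig_id, h.start))


def _divergent_partner(
    gene: GeneModel,
    box: ScanHit,
    genes_by_id: Mapping[str, GeneModel],
    windows_by_id: Mapping[str, PromoterWindow],
    assignments: Mapping[str, list[ScanHit]],
) -> str | None:
    """Find a divergently transcribed neighbour sharing ``box`` through the
    intergenic span between the two genes."""
    window = windows_by_id[gene.gene_id]
    for other_id, other_hits in assignments.items():
        if other_id == gene.gene_id:
            continue
        other = genes_by_id[other_id]
        if other.contig_id != gene.contig_id or other.strand == gene.strand:
            continue
        ow = windows_by_id[other_id]
        if ow.end <= window.start or window.end <= ow.start:
            continue  # windows must overlap
        if not any(h.contig_id == box.contig_id and h.start == box.start
                   and h.end == box.end for h in distinct_boxes(other_hits)):
            continue
        # box must lie in the intergenic span between the two gene bodies
        left, right = sorted([gene.extent, other.extent])
        if left[1] <= box.start and box.end <= right[0]:
            return other_id
    return None


def classify(
    assignments: Mapping[str, list[ScanHit]],
    genes: Sequence[GeneModel],
    clusters: Sequence[GeneCluster] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    windows: Sequence[PromoterWindow] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[CandidateAssignment]:
    """Assign each candidate gene exactly one location group (A > B > C > D).

    ``windows`` (or ``contig_lengths`` to rebuild them) are needed for the
    group-C divergence test; without them C collapses into D.
    """
    genes_by_id = {g.gene_id: g for g in genes}
    if clusters is None:
        clusters = build_clusters(genes, max_gap)
    cluster_of = {gid: c for c in clusters for gid in c.gene_ids}
    if windows is None and contig_lengths is not None:
        windows = build_promoter_windows(genes, contig_lengths)
    windows_by_id = {w.gene_id: w for w in windows} if windows else {}

    # distinct-box count pooled over each cluster's member genes
    cluster_boxes: dict[tuple[str, ...], int] = {}
    for c in clusters:
        pooled = [h for gid in c.gene_ids for h in assignments.get(gid, [])]
        cluster_boxes[c.gene_ids] = len(distinct_boxes(pooled))

    out: list[CandidateAssignment] = []
    for gene_id in sorted(assignments):
        gene_hits = assignments[gene_id]
        if not gene_hits:
            continue
        gene = genes_by_id[gene_id]
        boxes = distinct_boxes(gene_hits)
        best = rank_boxes(boxes)[0]
        cluster = cluster_of.get(gene_id)
        shared: str | None = None
        if cluster is not None and len(cluster) >= 2 and cluster_boxes[cluster.gene_ids] >= 2:
            group = "A"
        elif len(boxes) >= 2:
            group = "B"
        else:
            partner = None
            if windows_by_id:
                partner = _divergent_partner(gene, boxes[0], genes_by_id,
                                             windows_by_id, assignments)
            if partner is not None:
                group, shared = "C", partner
            else:
                group = "D"
        out.append(CandidateAssignment(gene_id, boxes, group, best, shared))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Genes from GFF3 CDS/gene features; start codon = strand-appropriate end."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    featuretypes = set(db.featuretypes())
    use = "CDS" if "CDS" in featuretypes else "gene"
    for feat in db.features_of_type(use, order_by="start"):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or [f"{use}_{feat.start}_{feat.end}"])[0]
        start0, end0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if feat.strand == "-":
            genes.append(GeneModel(gene_id, feat.seqid, "-", end0 - 1, start0))
        else:
            genes.append(GeneModel(gene_id, feat.seqid, "+", start0, end0))
    if not genes:
        raise ValueError(f"no {use} features found in {path}")
    return genes


def read_genes_genbank(path: str | Path) -> list[GeneModel]:
    """Genes from GenBank CDS features."""
    from Bio import SeqIO

    genes: list[GeneModel] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = (quals.get("gene") or quals.get("locus_tag")
                       or [f"cds_{int(feat.location.start)}"])[0]
            start0, end0 = int(feat.location.start), int(feat.location.end)
            if feat.location.strand == -1:
                genes.append(GeneModel(gene_id, rec.id, "-", end0 - 1, start0))
            else:
                genes.append(GeneModel(gene_id, rec.id, "+", start0, end0))
    if not genes:
        raise ValueError(f"no CDS features found in {path}")
    return genes


def write_candidates_tsv(candidates: Sequence[CandidateAssignment],
                         path: str | Path) -> None:
    """Candidate table; best-box coordinates are 1-based inclusive."""
    with Path(path).open("w") as fh:
        fh.write("gene\tgroup\tn_boxes\tbest_box_contig\tbest_box_start1\t"
                 "best_box_end1\tbest_box_strand\tbest_box_score\t"
                 "best_box_sequence\tshared_with\n")
        for c in candidates:
            b = c.best_box
            fh.write(
                f"{c.gene_id}\t{c.group}\t{len(c.boxes)}\t{b.contig_id}\t"
                f"{b.start + 1}\t{b.end}\t{b.strand}\t{b.score:.6g}\t"
                f"{b.sequence}\t{c.shared_with or ''}\n"
            )


def write_boxes_bed(candidates: Sequence[CandidateAssignment],
                    path: str | Path) -> None:
    """BED6 of every associated box, named gene|rank (rank 1 = best box)."""
    with Path(path).open("w") as fh:
        for c in candidates:
            for rank, box in enumerate(rank_boxes(c.boxes), start=1):
                fh.write(
                    f"{box.contig_id}\t{box.start}\t{box.end}\t"
                    f"{c.gene_id}|{rank}\t0\t{box.strand}\n"
                )
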