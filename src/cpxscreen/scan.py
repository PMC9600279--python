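"""Whole-genome PSSM scanning with an adaptive mean-minus-SD threshold.

Every fixed-length window of the genome is scored on the requested strands;
windows containing ambiguous bases are skipped and counted.  The score
population of all scoreable windows defines the adaptive cutoff
``tau = mu - sigma`` (population SD, divisor n: the windows are fully
enumerated, not sampled), and putative binding sites are the windows scoring
strictly above tau.  The 15-bp and 16-bp matrices are scanned and calibrated
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .motif import (
    ALPHABET,
    ScoringMatrix,
    reverse_complement,
    score_window,
)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: id, sequence over {A,C,G,T,N}, optional circularity."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanHit:
    """A putative binding site: one window scoring above the cutoff."""

    contig_id: str
    start: int  # 0-based forward-strand coordinate
    length: int
    strand: str  # "+" or "-"
    score: float  # bits
    sequence: str  # as read 5'->3' on its strand

    @property
    def end(self) -> int:
        return self.start + self.length

    def overlaps(self, other: "ScanHit") -> bool:
        return (self.contig_id == other.contig_id
                and self.start < other.end and other.start < self.end)


@dataclass
class ScanResult:
    """Hits plus the score-population statistics behind the threshold."""

    hits: list[ScanHit]
    mean: float
    sd: float
    threshold: float
    n_windows: int
    n_skipped: int = 0
    matrix_length: int = 0

    def summary(self) -> dict:
        return {
            "matrix_length": self.matrix_length,
            "mean": self.mean,
            "sd": self.sd,
            "threshold": self.threshold,
            "n_windows": self.n_windows,
            "n_skipped": self.n_skipped,
            "n_hits": len(self.hits),
        }


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_CHUNK = 1 << 20  # windows per gather chunk, bounds peak memory on long contigs


def _window_scores(matrix: ScoringMatrix, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and validity mask for all length-k windows of an encoded sequence.

    Each window score is an exactly rounded sum of its k cells (math.fsum),
    bit-identical to :func:`cpxscreen.motif.score_window` on the same window.
    """
    k = matrix.length
    n_win = enc.size - k + 1
    if n_win <= 0:
        raise ValueError(f"sequence shorter than matrix length {k}")
    scores = np.empty(n_win, dtype=float)
    valid = np.ones(n_win, dtype=bool)
    lut = np.asarray(matrix.scores, dtype=float)  # (k, 4)
    lut5 = np.concatenate([lut, np.zeros((k, 1))], axis=1)  # code 4 scores 0, masked out
    fsum = math.fsum
    for lo in range(0, n_win, _CHUNK):
        hi = min(lo + _CHUNK, n_win)
        codes = np.lib.stride_tricks.sliding_window_view(enc[lo:hi + k - 1], k)
        valid[lo:hi] = ~(codes == 4).any(axis=1)
        contrib = lut5[np.arange(k), codes]  # (chunk, k)
        scores[lo:hi] = [fsum(row) for row in contrib]
    return scores, valid


def enumerate_window_scores(
    matrix: ScoringMatrix,
    genome: GenomeSequence,
    strands: Sequence[str] = ("+", "-"),
) -> Iterator[tuple[int, str, float]]:
    """Yield (start, strand, score) for every scoreable window.

    Minus-strand windows are scored on the reverse complement and reported at
    the forward-strand coordinate of the window.  Windows containing any
    non-ACGT base are skipped.  For circular contigs, windows wrap across the
    origin (starts in [0, L)).
    """
    for start, strand, score in _scored_windows(matrix, genome, strands)[0]:
        yield start, strand, score


def _scored_windows(
    matrix: ScoringMatrix,
    genome: GenomeSequence,
    strands: Sequence[str],
) -> tuple[list[tuple[int, str, float]], int]:
    for s in strands:
        if s not in ("+", "-"):
            raise ValueError(f"unknown strand {s!r}")
    k = matrix.length
    seq = genome.sequence
    if genome.circular:
        seq = seq + genome.sequence[: k - 1]
        n_starts = len(genome)
    else:
        if len(seq) < k:
            raise ValueError(
                f"contig {genome.contig_id!r} ({len(seq)} bp) is shorter than "
                f"the matrix ({k} bp)"
            )
        n_starts = len(seq) - k + 1
    enc = encode_sequence(seq)
    records: list[tuple[int, str, float]] = []
    n_skipped = 0
    for strand in strands:
        mat = matrix if strand == "+" else matrix.reverse_complement()
        scores, valid = _window_scores(mat, enc)
        scores, valid = scores[:n_starts], valid[:n_starts]
        n_skipped += int((~valid).sum())
        for start in np.flatnonzero(valid):
            records.append((int(start), strand, float(scores[start])))
    return records, n_skipped


def calibrate_threshold(scores: Iterable[float]) -> tuple[float, float, float]:
    """(mu, sigma, tau) with tau = mu - sigma; sigma is the population SD."""
    arr = np.fromiter((float(s) for s in scores), dtype=float)
    if arr.size < 2:
        raise ValueError("threshold calibration needs at least 2 scores")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=0))
    return mu, sigma, mu - sigma


def filter_hits(
    scored_windows: Iterable[tuple[int, str, float]],
    threshold: float,
    genome: GenomeSequence,
    matrix_length: int,
) -> list[ScanHit]:
    """Keep windows scoring strictly above the cutoff, sorted by locus."""
    hits = []
    seq = genome.sequence
    if genome.circular:
        seq = seq + genome.sequence[: matrix_length - 1]
    for start, strand, score in scored_windows:
        if score > threshold:
            window = seq[start:start + matrix_length]
            if strand == "-":
                window = reverse_complement(window)
            hits.append(ScanHit(genome.contig_id, start, matrix_length, strand, score, window))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def scan_genome(
    matrix: ScoringMatrix,
    genomes: GenomeSequence | Sequence[GenomeSequence],
    strands: Sequence[str] = ("+", "-"),
    threshold: float | None = None,
) -> ScanResult:
    """Scan one matrix over one or more contigs and apply the adaptive cutoff.

    When ``threshold`` is given it overrides the mean-minus-SD rule (the
    population statistics are still reported).
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    ids = [g.contig_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique within a scan")
    per_contig: list[tuple[GenomeSequence, list[tuple[int, str, float]]]] = []
    n_skipped = 0
    all_scores: list[np.ndarray] = []
    for genome in genomes:
        records, skipped = _scored_windows(matrix, genome, strands)
        per_contig.append((genome, records))
        n_skipped += skipped
        all_scores.append(np.array([r[2] for r in records], dtype=float))
    pooled = np.concatenate(all_scores) if all_scores else np.empty(0)
    if threshold is None:
        mu, sigma, cutoff = calibrate_threshold(pooled)
    else:
        # fixed cutoff: population statistics still reported when defined
        mu = float(pooled.mean()) if pooled.size else float("nan")
        sigma = float(pooled.std(ddof=0)) if pooled.size else float("nan")
        cutoff = float(threshold)
    hits: list[ScanHit] = []
    for genome, records in per_contig:
        hits.extend(filter_hits(records, cutoff, genome, matrix.length))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return ScanResult(hits, mu, sigma, cutoff, int(pooled.size), n_skipped, matrix.length)


def scan(
    matrix15: ScoringMatrix,
    matrix16: ScoringMatrix,
    genomes: GenomeSequence | Sequence[GenomeSequence],
    strands: Sequence[str] = ("+", "-"),
) -> tuple[ScanResult, ScanResult]:
    """Run the paired 15-bp and 16-bp screens, calibrated independently."""
    if matrix15.length != 15 or matrix16.length != 16:
        raise ValueError("expected matrices of length 15 and 16")
    return (scan_genome(matrix15, genomes, strands),
            scan_genome(matrix16, genomes, strands))


# ---------------------------------------------------------------------------
# I/O


def read_genome(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    """Read contigs from FASTA or GenBank (by extension)."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    contigs = [
        GenomeSequence(rec.id, str(rec.seq).upper(), circular)
        for rec in SeqIO.parse(str(path), fmt)
    ]
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return contigs


def bed_score(score_bits: float, max_score: float) -> int:
    """Clamp/scale a bit score into the BED score column's 0-1000 range."""
    if max_score <= 0:
        return 0
    return int(round(min(max(score_bits, 0.0), max_score) / max_score * 1000))


def write_hits_bed(hits: Sequence[ScanHit], path: str | Path, max_score: float) -> None:
    """BED6; the name column tags the matrix length."""
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\tpssm{h.length}\t"
                f"{bed_score(h.score, max_score)}\t{h.strand}\n"
            )


def write_hits_tsv(hits: Sequence[ScanHit], path: str | Path) -> None:
    """Lossless hit table (0-based half-open coordinates)."""
    with Path(path).open("w") as fh:
        fh.write("contig\tstart0\tend0\tstrand\tlength\tscore_bits\tsequence\n")
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.length}\t"
                f"{h.score:.6g}\t{h.sequence}\n"
            )


def read_hits_tsv(path: str | Path) -> list[ScanHit]:
    hits = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(ScanHit(
                f[idx["contig"]], int(f[idx["start0"]]),
                int(f[idx["length"]]), f[idx["strand"]],
                float(f[idx["score_bits"]]), f[idx["sequence"]],
            ))
    return hits
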