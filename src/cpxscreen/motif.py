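"""Position-specific scoring matrices for the bipartite CpxR box.

CpxR, the response regulator of the CpxRA envelope-stress two-component
system, recognises a gapped motif of two pentamers separated by a 5- or
6-bp spacer (consensus GTAAA-N5/6-GTAAA).  This module builds the motif
model from a collection of aligned known binding sites:

* base counts per column,
* a position weight matrix (PWM) of probabilities with an additive
  pseudocount ``beta`` (default 0.5, shared equally by the four bases, so
  ``p = (n + beta) / (N + 4 beta)``),
* a position-specific scoring matrix (PSSM) of log2-odds scores in bits
  against a background base distribution (uniform by default).

A window's score is the sum of its per-position cells; the spacer-expansion
rule (duplicating the middle base of the 5-bp spacer) converts the 15-bp
training set into a 16-bp one, compensating for the scarcity of curated
16-bp sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _validate_dna(seq: str, *, context: str = "sequence") -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"{context} contains non-ACGT characters {sorted(bad)!r}; "
            "ambiguity codes are not allowed in training sites"
        )


@dataclass(frozen=True)
class BindingSiteCollection:
    """Aligned known binding sites of one shared length (15 or typically 16)."""

    sites: tuple[str, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("binding-site collection must be non-empty")
        lengths = {len(s) for s in self.sites}
        if len(lengths) != 1:
            raise ValueError(f"ragged site lengths {sorted(lengths)}; all sites must align")
        for s in self.sites:
            _validate_dna(s, context="binding site")
        if self.labels is not None and len(self.labels) != len(self.sites):
            raise ValueError("labels must match sites one-to-one")

    @property
    def site_length(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_sequences(cls, sites: Iterable[str], labels: Iterable[str] | None = None
                       ) -> "BindingSiteCollection":
        return cls(tuple(str(s).upper() for s in sites),
                   tuple(labels) if labels is not None else None)


@dataclass(frozen=True)
class BackgroundModel:
    """Background base frequencies q(b), summing to one."""

    q: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        arr = np.asarray(self.q, dtype=float)
        if arr.shape != (4,) or np.any(arr <= 0):
            raise ValueError("background needs four strictly positive frequencies")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {arr.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def from_sequence(cls, seq: str) -> "BackgroundModel":
        """Empirical composition of a scanned sequence (non-ACGT bases ignored)."""
        counts = np.array([seq.count(b) for b in ALPHABET], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError("sequence has no ACGT bases")
        return cls(tuple(counts / total))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float)


@dataclass(frozen=True)
class NucleotideCountMatrix:
    """Per-(position, base) occurrence counts over a site collection."""

    counts: np.ndarray  # shape (length, 4), ints
    n_sites: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(counts.sum(axis=1) == self.n_sites):
            raise ValueError("each column of counts must sum to n_sites")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-(position, base) probabilities; columns sum to one."""

    probabilities: np.ndarray  # shape (length, 4)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probabilities must have shape (length, 4)")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("each position's probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]


@dataclass(frozen=True)
class ScoringMatrix:
    """Log2-odds scores (bits) per (position, base) against a background."""

    scores: np.ndarray  # shape (length, 4), bits
    background: BackgroundModel = field(default_factory=BackgroundModel)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4:
            raise ValueError("scores must have shape (length, 4)")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite; use a pseudocount > 0")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        """Highest achievable window score (sum of per-position maxima)."""
        return float(np.asarray(self.scores).max(axis=1).sum())

    def reverse_complement(self) -> "ScoringMatrix":
        """Matrix scoring the reverse-complement strand at the same coordinates."""
        s = np.asarray(self.scores)
        return ScoringMatrix(s[::-1, ::-1].copy(), self.background)


def build_count_matrix(sites: BindingSiteCollection) -> NucleotideCountMatrix:
    """Tally base occurrences per alignment column."""
    length = sites.site_length
    counts = np.zeros((length, 4), dtype=int)
    for site in sites.sites:
        for pos, base in enumerate(site):
            counts[pos, BASE_INDEX[base]] += 1
    return NucleotideCountMatrix(counts, len(sites))


def expand_spacer(site15: str) -> str:
    """Duplicate the middle spacer base of a 15-bp site, yielding 16 bp.

    For pentamer-N5-pentamer sites the middle of the spacer is the 8th base
    (0-based index 7); duplicating it emulates the N6 spacer variant.
    """
    if len(site15) != 15:
        raise ValueError(f"expected a 15-bp site, got {len(site15)} bp")
    _validate_dna(site15, context="site")
    return site15[:8] + site15[7] + site15[8:]


def expand_collection(sites: BindingSiteCollection) -> BindingSiteCollection:
    """Apply the spacer-expansion rule to every 15-bp site of a collection."""
    if sites.site_length != 15:
        raise ValueError("spacer expansion applies to 15-bp collections only")
    return BindingSiteCollection(tuple(expand_spacer(s) for s in sites.sites), sites.labels)


def build_pwm(counts: NucleotideCountMatrix, pseudocount: float = 0.5,
              background: BackgroundModel | None = None,
              allocation: str = "uniform") -> PositionWeightMatrix:
    """Normalise counts to probabilities with an additive pseudocount.

    allocation="uniform" shares beta equally: p = (n + beta) / (N + 4 beta).
    allocation="background" weights it by q(b): p = (n + 4 beta q(b)) / (N + 4 beta).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    n = counts.counts.astype(float)
    if allocation == "uniform":
        extra = pseudocount
    elif allocation == "background":
        q = (background or BackgroundModel()).as_array()
        extra = 4.0 * pseudocount * q
    else:
        raise ValueError(f"unknown pseudocount allocation {allocation!r}")
    p = (n + extra) / (counts.n_sites + 4.0 * pseudocount)
    return PositionWeightMatrix(p, pseudocount)


def build_pssm(pwm: PositionWeightMatrix,
               background: BackgroundModel | None = None) -> ScoringMatrix:
    """Log2-odds matrix s(i, b) = log2(p(i, b) / q(b)), in bits."""
    background = background or BackgroundModel()
    p = np.asarray(pwm.probabilities, dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "PWM contains a zero probability (infinite log-odds); "
            "rebuild it with a pseudocount > 0"
        )
    scores = np.log2(p / background.as_array())
    return ScoringMatrix(scores, background)


def build_matrix_from_sites(sites: BindingSiteCollection, pseudocount: float = 0.5,
                            background: BackgroundModel | None = None,
                            allocation: str = "uniform") -> ScoringMatrix:
    """Convenience: counts -> PWM -> PSSM in one call."""
    counts = build_count_matrix(sites)
    pwm = build_pwm(counts, pseudocount, background=background, allocation=allocation)
    return build_pssm(pwm, background)


def score_window(matrix: ScoringMatrix, window: str) -> float:
    """Score a window as the sum of per-position matrix cells (bits).

    The sum is exactly rounded (math.fsum), so the result is independent of
    summation order; scoring a reverse-complemented window against the
    reverse-complement matrix is bit-identical to the forward score.
    """
    if len(window) != matrix.length:
        raise ValueError(
            f"window length {len(window)} does not match matrix length {matrix.length}"
        )
    _validate_dna(window, context="window")
    s = np.asarray(matrix.scores)
    return math.fsum(s[i, BASE_INDEX[b]] for i, b in enumerate(window))


def consensus(pwm: PositionWeightMatrix) -> str:
    """Per-column argmax base; ties resolved by fixed base order A<C<G<T."""
    # np.argmax takes the first maximum, which is the A<C<G<T order by construction
    idx = np.argmax(np.asarray(pwm.probabilities), axis=1)
    return "".join(ALPHABET[i] for i in idx)


# ---------------------------------------------------------------------------
# I/O: sites files and matrix TSV + JSON sidecar


def read_sites(path: str | Path) -> BindingSiteCollection:
    """Read aligned sites from FASTA or one-sequence-per-line text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return BindingSiteCollection.from_sequences(
            (str(r.seq) for r in records), (r.id for r in records)
        )
    lines = [ln.strip() for ln in text.splitlines()]
    return BindingSiteCollection.from_sequences(ln for ln in lines if ln and not ln.startswith("#"))


def write_matrix(matrix: ScoringMatrix, path: str | Path, *,
                 pseudocount: float | None = None, kind: str = "bits") -> None:
    """Write a matrix as TSV (`pos A C G T`) plus a JSON sidecar of metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for i, row in enumerate(np.asarray(matrix.scores)):
            fh.write(f"{i}\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "kind": kind,
        "alphabet": ALPHABET,
        "length": matrix.length,
        "background": list(matrix.background.q),
        "pseudocount": pseudocount,
        "log_base": 2,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_matrix(path: str | Path) -> ScoringMatrix:
    """Read a matrix TSV written by :func:`write_matrix`."""
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        header = fh.readline().split()
        if header != ["pos", "A", "C", "G", "T"]:
            raise ValueError(f"unexpected matrix header {header!r}")
        for line in fh:
            parts = line.split()
            rows.append([float(x) for x in parts[1:5]])
    sidecar_path = path.with_suffix(path.suffix + ".json")
    background = BackgroundModel()
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        background = BackgroundModel(tuple(meta["background"]))
    return ScoringMatrix(np.asarray(rows, dtype=float), background)
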