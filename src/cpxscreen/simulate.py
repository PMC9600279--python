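"""Seeded synthetic inputs with known truth for every pipeline stage.

Three generators emulate the screen's inputs:

* :func:`sample_sites` — noisy binding sites around the bipartite
  GTAAA-N5-GTAAA consensus (each flank base kept with identity probability
  ``pi``, otherwise substituted uniformly among the other three bases;
  spacer bases i.i.d. uniform),
* :func:`plant_genome` — an i.i.d.-background genome with gene models and
  consensus boxes planted in promoter windows laid out per the four
  location-group classes (A: cluster with two boxes; B: two boxes before
  one gene; C: one box shared by a divergent pair; D: one box before one
  gene), with a truth table for recovery scoring,
* :func:`simulate_ct` — qPCR Ct tables with stated per-gene log2 effects
  and Gaussian replicate noise on the cycle scale.

All generators are pure functions of (spec, seed): same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import ALPHABET, BindingSiteCollection
from .promoters import GeneModel, build_promoter_windows
from .regulation import CtTable
from .scan import GenomeSequence

#: E. coli-like base composition (GC ~= 0.508)
ECOLI_BACKGROUND = (0.246, 0.254, 0.254, 0.246)


@dataclass(frozen=True)
class MotifSpec:
    """Sampling model for binding sites around the bipartite consensus."""

    left_pentamer: str = "GTAAA"
    right_pentamer: str = "GTAAA"
    spacer_probs: Mapping[int, float] = field(default_factory=lambda: {5: 1.0})
    identity_prob: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.left_pentamer, self.right_pentamer):
            if len(p) != 5 or set(p) - set(ALPHABET):
                raise ValueError(f"pentamer {p!r} must be 5 bases over ACGT")
        if not 0 < self.identity_prob <= 1:
            raise ValueError("identity probability must be in (0, 1]")
        if set(self.spacer_probs) - {5, 6}:
            raise ValueError("spacer lengths must be 5 or 6")
        if abs(sum(self.spacer_probs.values()) - 1.0) > 1e-9:
            raise ValueError("spacer length probabilities must sum to 1")

def _mutate(rng: np.random.Generator, base: str, pi: float) -> str:
    if rng.random() < pi:
        return base
    others = [b for b in ALPHABET if b != base]
    return others[rng.integers(3)]


def sample_sites(spec: MotifSpec, n: int, seed: int) -> BindingSiteCollection:
    """Draw ``n`` aligned sites; the spacer distribution must be degenerate
    (all 5 or all 6) because aligned collections share one length."""
    if n < 1:
        raise ValueError("need at least one site")
    lengths = {k for k, p in spec.spacer_probs.items() if p > 0}
    if len(lengths) != 1:
        raise ValueError(
            "mixed 5/6-bp spacer sampling would produce a ragged alignment; "
            "sample each length separately (or derive the 16-bp set by "
            "spacer expansion)"
        )
    spacer_len = lengths.pop()
    rng = np.random.default_rng(seed)
    sites = []
    for _ in range(n):
        flank_l = "".join(_mutate(rng, b, spec.identity_prob)
                          for b in spec.left_pentamer)
        spacer = "".join(ALPHABET[i] for i in rng.integers(4, size=spacer_len))
        flank_r = "".join(_mutate(rng, b, spec.identity_prob)
                          for b in spec.right_pentamer)
        sites.append(flank_l + spacer + flank_r)
    return BindingSiteCollection(tuple(sites))


def _sample_one_site(rng: np.random.Generator, spec: MotifSpec) -> str:
    lengths = sorted(k for k, p in spec.spacer_probs.items() if p > 0)
    probs = [spec.spacer_probs[k] for k in lengths]
    spacer_len = int(rng.choice(lengths, p=probs))
    flank_l = "".join(_mutate(rng, b, spec.identity_prob) for b in spec.left_pentamer)
    spacer = "".join(ALPHABET[i] for i in rng.integers(4, size=spacer_len))
    flank_r = "".join(_mutate(rng, b, spec.identity_prob) for b in spec.right_pentamer)
    return flank_l + spacer + flank_r


@dataclass(frozen=True)
class PlantedSite:
    contig_id: str
    start: int
    end: int
    strand: str
    layout_class: str  # intended location group A-D
    gene_ids: tuple[str, ...]

    @property
    def sequence_length(self) -> int:
        return self.end - self.start


@dataclass
class PlantedGenomeTruth:
    """A synthetic genome, its gene models, and the planted-site truth table."""

    genome: GenomeSequence
    genes: list[GeneModel]
    planted: list[PlantedSite]
    background: tuple[float, float, float, float]
    seed: int

    def write(self, outdir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
        """Emit FASTA + GFF3 + truth BED6 (class label in the name field)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        with fasta.open("w") as fh:
            fh.write(f">{self.genome.contig_id} seed={self.seed}\n")
            seq = self.genome.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
        gff = outdir / f"{prefix}.gff3"
        with gff.open("w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.genome.contig_id} 1 {len(self.genome)}\n")
            for g in self.genes:
                left, right = g.extent
                fh.write(
                    f"{g.contig_id}\tcpxscreen\tCDS\t{left + 1}\t{right}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )
        bed = outdir / f"{prefix}_truth.bed"
        with bed.open("w") as fh:
            for s in self.planted:
                name = f"{s.layout_class}|{','.join(s.gene_ids)}"
                fh.write(f"{s.contig_id}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\n")
        return {"fasta": fasta, "gff3": gff, "truth_bed": bed}


def _random_sequence(rng: np.random.Generator, length: int,
                     background: Sequence[float]) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(background, dtype=float))


def plant_genome(
    site_spec: MotifSpec,
    n_genes: int = 0,
    genome_length: int = 50_000,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    class_layout: Mapping[str, int] | None = None,
    seed: int = 0,
    gene_length: int = 600,
    upstream: int = 700,
    downstream: int = 100,
) -> PlantedGenomeTruth:
    """Plant box layouts for the requested location-group classes.

    ``class_layout`` maps class letters to exemplar counts, e.g.
    ``{"A": 1, "B": 1, "C": 1, "D": 1}``.  ``n_genes`` additional box-free
    genes are appended.  Layout units are spaced so promoter windows of
    different units never overlap; an infeasible request raises.
    """
    class_layout = dict(class_layout or {})
    if set(class_layout) - set("ABCD"):
        raise ValueError("layout classes must be among A, B, C, D")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, genome_length, background)
    contig = "synthetic_1"

    genes: list[GeneModel] = []
    planted: list[PlantedSite] = []
    cursor = upstream + 50  # leave room for the first promoter window
    counter = 0

    def put_site(pos: int, layout: str, gene_ids: tuple[str, ...]) -> None:
        site = _sample_one_site(rng, site_spec)
        enc = np.array([ALPHABET.index(b) for b in site], dtype=seq.dtype)
        if pos < 0 or pos + len(site) > genome_length:
            raise ValueError("infeasible layout: planted site outside the genome")
        seq[pos:pos + len(site)] = enc
        planted.append(PlantedSite(contig, pos, pos + len(site), "+", layout, gene_ids))

    def new_gene(start: int, strand: str) -> GeneModel:
        nonlocal counter
        counter += 1
        gid = f"g{counter:03d}"
        if strand == "+":
            gene = GeneModel(gid, contig, "+", start, start + gene_length)
        else:
            gene = GeneModel(gid, contig, "-", start, start - gene_length)
        genes.append(gene)
        return gene

    unit_pad = upstream + downstream + 60  # clearance so windows never overlap units

    for layout in sorted(class_layout):
        for _ in range(class_layout[layout]):
            if layout == "A":
                # two-gene same-strand cluster, two boxes in the lead gene's window
                g1 = new_gene(cursor, "+")
                new_gene(cursor + gene_length + 30, "+")
                put_site(cursor - 420, "A", (g1.gene_id,))
                put_site(cursor - 180, "A", (g1.gene_id,))
                cursor += 2 * gene_length + 30 + unit_pad
            elif layout == "B":
                g = new_gene(cursor, "+")
                put_site(cursor - 450, "B", (g.gene_id,))
                put_site(cursor - 150, "B", (g.gene_id,))
                cursor += gene_length + unit_pad
            elif layout == "C":
                # divergent pair: left gene on -, right gene on +, shared box between
                left_start = cursor + gene_length - 1  # start codon of the minus gene
                gl = new_gene(left_start, "-")
                right_start = left_start + 301
                gr = new_gene(right_start, "+")
                mid = (left_start + right_start) // 2 - 8
                gr_gene = gr
                put_site(mid, "C", (gl.gene_id, gr_gene.gene_id))
                cursor = right_start + gene_length + unit_pad
            elif layout == "D":
                g = new_gene(cursor, "+")
                put_site(cursor - 300, "D", (g.gene_id,))
                cursor += gene_length + unit_pad
            if cursor > genome_length:
                raise ValueError("infeasible layout: genome too short for the request")

    for _ in range(n_genes):
        new_gene(cursor, "+")
        cursor += gene_length + unit_pad
        if cursor > genome_length:
            raise ValueError("infeasible layout: genome too short for the request")

    genome = GenomeSequence(contig, "".join(ALPHABET[i] for i in seq))
    truth = PlantedGenomeTruth(genome, genes, planted,
                               tuple(float(x) for x in background), seed)
    # every planted site must sit inside >= 1 promoter window (truth invariant)
    windows = build_promoter_windows(genes, {contig: genome_length},
                                     upstream, downstream)
    for site in truth.planted:
        containing = [w.gene_id for w in windows
                      if w.start <= site.start and site.end <= w.end]
        if not set(site.gene_ids) <= set(containing):
            raise ValueError(
                f"planted site {site} escaped its promoter window(s); "
                "layout parameters are infeasible"
            )
    return truth


@dataclass(frozen=True)
class SimulatedExpressionSpec:
    """Per-gene true log2 effects per condition, plus replicate noise."""

    effects: Mapping[str, Mapping[str, float]]  # gene -> condition -> log2 effect
    conditions: tuple[str, ...]
    noise_sd: float = 0.0  # Ct cycles
    n_replicates: int = 3
    baseline_ct: float = 20.0
    reference_gene: str = "rpoD"
    reference_ct: float = 15.0
    control_condition: str = "control"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_ct(spec: SimulatedExpressionSpec, seed: int) -> CtTable:
    """Ct table with Ct = baseline - effect(log2) + Gaussian noise.

    The reference gene has zero effect everywhere, so a gene's expected
    ΔΔCt fold equals ``2**effect``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_conditions = (spec.control_condition,) + tuple(
        c for c in spec.conditions if c != spec.control_condition)
    gene_list = [spec.reference_gene] + [g for g in spec.effects
                                         if g != spec.reference_gene]
    for gene in gene_list:
        base = spec.reference_ct if gene == spec.reference_gene else spec.baseline_ct
        for condition in all_conditions:
            if gene == spec.reference_gene or condition == spec.control_condition:
                effect = 0.0
            else:
                effect = float(spec.effects[gene].get(condition, 0.0))
            for rep in range(1, spec.n_replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                rows.append((gene, condition, rep, base - effect + noise))
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return CtTable(df, spec.reference_gene, spec.control_condition)
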