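"""ΔΔCt fold changes and two-fold regulation calls per activation group.

Relative expression is quantified with the ΔΔCt method against a
constitutive reference gene (rpoD by default):

    ΔΔCt = (Ct_gene - Ct_ref)_condition - (Ct_gene - Ct_ref)_control
    fold  = 2 ** (-ΔΔCt)

Replicate Ct values are averaged (arithmetic mean of cycles) before the
contrast.  A gene is called regulated in an activation group when either of
the group's condition columns shows a two-fold difference in either
direction (fold >= 2 up, fold <= 0.5 down; bounds inclusive — "<2-fold"
defines insignificance).  The two activation groups of the Cpx screen are
the cpxA-allele panel (cpxA24, ΔcpxA) and the NlpE-overexpression panel
(p-nlpE, ΔcpxR p-nlpE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
INSIGNIFICANT = "insignificant"

#: condition columns of the two CpxRA-activation groups
GROUP_CPXA = ("cpxA24", "dcpxA")
GROUP_NLPE = ("pnlpE", "dcpxR_pnlpE")
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "cpxA_alleles": GROUP_CPXA,
    "nlpE_overexpression": GROUP_NLPE,
}


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements: (gene, condition, replicate, ct)."""

    data: pd.DataFrame
    reference_gene: str = "rpoD"
    control_condition: str = "control"

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table is missing columns {sorted(missing)}")
        ct = self.data["ct"]
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be finite positive reals")
        ref_conditions = set(self.data.loc[self.data["gene"] == self.reference_gene,
                                           "condition"])
        all_conditions = set(self.data["condition"])
        if not all_conditions <= ref_conditions:
            raise ValueError(
                f"reference gene {self.reference_gene!r} must be measured in "
                f"every condition (missing {sorted(all_conditions - ref_conditions)})"
            )

    def mean_ct(self, gene: str, condition: str) -> float:
        sel = self.data[(self.data["gene"] == gene)
                        & (self.data["condition"] == condition)]
        if sel.empty:
            raise KeyError(f"no Ct measurements for gene {gene!r} in {condition!r}")
        return float(sel["ct"].mean())

    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]

    def conditions(self) -> list[str]:
        return [c for c in self.data["condition"].unique()
                if c != self.control_condition]

    @classmethod
    def read_tsv(cls, path: str | Path, reference_gene: str = "rpoD",
                 control_condition: str = "control") -> "CtTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df, reference_gene, control_condition)


def ddct_fold(ct: CtTable, gene: str, condition: str,
              per_replicate: bool = False) -> float:
    """Fold change 2^(-ΔΔCt) of ``gene`` in ``condition`` versus the control.

    ``per_replicate=True`` averages per-replicate folds (geometry differs
    only at high replicate variance); the default contrasts replicate-mean
    Ct values.
    """
    if per_replicate:
        folds = per_replicate_folds(ct, gene, condition)
        return float(np.mean(folds))
    ddct = ((ct.mean_ct(gene, condition) - ct.mean_ct(ct.reference_gene, condition))
            - (ct.mean_ct(gene, ct.control_condition)
               - ct.mean_ct(ct.reference_gene, ct.control_condition)))
    return float(2.0 ** (-ddct))


def per_replicate_folds(ct: CtTable, gene: str, condition: str) -> list[float]:
    """Fold per condition replicate, against replicate-mean control baselines."""
    base = (ct.mean_ct(gene, ct.control_condition)
            - ct.mean_ct(ct.reference_gene, ct.control_condition))
    ref_cond = ct.mean_ct(ct.reference_gene, condition)
    sel = ct.data[(ct.data["gene"] == gene) & (ct.data["condition"] == condition)]
    if sel.empty:
        raise KeyError(f"no Ct measurements for gene {gene!r} in {condition!r}")
    return [float(2.0 ** (-((row_ct - ref_cond) - base))) for row_ct in sel["ct"]]


@dataclass
class FoldChangeTable:
    """Wide per-gene fold changes; NaN marks an insignificant/missing cell."""

    folds: pd.DataFrame  # index: gene, columns: condition ids
    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        for name, cols in self.groups.items():
            missing = set(cols) - set(self.folds.columns)
            if missing:
                raise ValueError(f"group {name!r} references missing columns {sorted(missing)}")
        vals = self.folds.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("fold changes must be positive")

    @classmethod
    def read_tsv(cls, path, groups: Mapping[str, tuple[str, ...]] | None = None
                 ) -> "FoldChangeTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene",
                         na_values=["—", "-", ""])
        return cls(df, dict(groups) if groups else dict(DEFAULT_GROUPS))

    def write_tsv(self, path: str | Path) -> None:
        out = self.folds.copy()
        with Path(path).open("w") as fh:
            fh.write("gene\t" + "\t".join(out.columns) + "\n")
            for gene, row in out.iterrows():
                cells = ["" if pd.isna(v) else format(v, "g") for v in row]
                fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_ct(cls, ct: CtTable,
                groups: Mapping[str, tuple[str, ...]] | None = None
                ) -> "FoldChangeTable":
        conditions = ct.conditions()
        rows = {gene: [ddct_fold(ct, gene, cond) for cond in conditions]
                for gene in ct.genes()}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
        df.index.name = "gene"
        if groups is None:
            groups = {"all": tuple(conditions)}
        return cls(df, dict(groups))


def call_column(fold: float | None, threshold: float = 2.0) -> str:
    """Verdict for one fold-change cell under the two-fold rule."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if fold is None or (isinstance(fold, float) and math.isnan(fold)):
        return INSIGNIFICANT
    if fold <= 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    if fold >= threshold:
        return POSITIVE
    if fold <= 1.0 / threshold:
        return NEGATIVE
    return INSIGNIFICANT


def _group_verdict(row: pd.Series, cols: Sequence[str], threshold: float) -> str:
    """Verdict of the most extreme significant column (largest |log2 fold|)."""
    best, best_mag = INSIGNIFICANT, -1.0
    for col in cols:
        fold = row.get(col)
        verdict = call_column(None if pd.isna(fold) else float(fold), threshold)
        if verdict != INSIGNIFICANT:
            mag = abs(math.log2(float(fold)))
            if mag > best_mag:
                best, best_mag = verdict, mag
    return best


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    verdicts: Mapping[str, str]  # group name -> positive/negative/insignificant

    @property
    def regulated(self) -> bool:
        return any(v != INSIGNIFICANT for v in self.verdicts.values())


def call_regulation(table: FoldChangeTable, threshold: float = 2.0
                    ) -> list[RegulationCall]:
    """Per-gene, per-group verdicts and the overall regulated flag."""
    calls = []
    for gene, row in table.folds.iterrows():
        verdicts = {name: _group_verdict(row, cols, threshold)
                    for name, cols in table.groups.items()}
        calls.append(RegulationCall(str(gene), verdicts))
    return calls


def count_regulated(table: FoldChangeTable, group: str,
                    threshold: float = 2.0) -> int:
    """Genes with a significant call in either of the group's columns."""
    if group not in table.groups:
        raise KeyError(f"unknown group {group!r}; have {sorted(table.groups)}")
    return sum(c.verdicts[group] != INSIGNIFICANT
               for c in call_regulation(table, threshold))


def count_union(table: FoldChangeTable, threshold: float = 2.0) -> int:
    """Distinct genes regulated in at least one activation group."""
    return sum(c.regulated for c in call_regulation(table, threshold))


def write_calls_tsv(calls: Sequence[RegulationCall], path: str | Path) -> None:
    groups = list(calls[0].verdicts) if calls else []
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(f"{g}_verdict" for g in groups)
                 + "\tregulated\n")
        for c in calls:
            fh.write(c.gene_id + "\t"
                     + "\t".join(c.verdicts[g] for g in groups)
                     + f"\t{str(c.regulated).lower()}\n")


# ---------------------------------------------------------------------------
# bundled fold-change fixtures (transcribed published qRT-PCR tables)


def _load_bundled(name: str) -> FoldChangeTable:
    with resources.as_file(resources.files("cpxscreen.data") / name) as p:
        return FoldChangeTable.read_tsv(p)


def load_screen_fold_changes() -> FoldChangeTable:
    """Fold changes of the 73 newly identified CpxR-regulated genes."""
    return _load_bundled("screen_fold_changes.tsv")


def load_known_gene_fold_changes() -> FoldChangeTable:
    """Fold changes of the previously reported positive-control genes."""
    return _load_bundled("known_gene_fold_changes.tsv")
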