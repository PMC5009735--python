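"""Integration of binding targets with differential-abundance and
differential-translation tables.

Differential-expression calling is consumed, never fitted: tables arrive as
(gene_id, log2fc, pvalue, padj) rows from an upstream negative-binomial fit.
Genes present in only one modality are treated as non-significant in the
missing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj"]


@dataclass
class DETable:
    df: pd.DataFrame
    modality: str  # "abundance" | "translation"
    contrast: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene_id must be unique per DE table")

    def significant(self, padj_threshold: float = 0.05) -> set[str]:
        return set(self.df.loc[self.df["padj"] < padj_threshold, "gene_id"])


def read_de_table(path: str | Path, modality: str, contrast: str = "") -> DETable:
    return DETable(pd.read_csv(path, sep="\t"), modality=modality, contrast=contrast)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding, matching how printed percentages are typically shown."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, total: int) -> float:
    return round_half_up(100.0 * n / total) if total else 0.0


@dataclass
class OverlapSummary:
    """Partition of differentially expressed genes by modality, overall and
    restricted to an iCLIP target set. Percentages of the overall block are of
    ``n_de_total``; percentages of the iCLIP block are of ``n_iclip_de``."""

    n_de_total: int
    n_rna: int
    n_ribo: int
    n_rna_only: int
    n_both: int
    n_ribo_only: int
    n_iclip_de: int
    n_iclip_rna: int
    n_iclip_ribo: int
    n_iclip_rna_only: int
    n_iclip_both: int
    n_iclip_ribo_only: int
    empty: bool = False

    def percentages(self) -> dict[str, float]:
        t, it = self.n_de_total, self.n_iclip_de
        return {
            "rna": _pct(self.n_rna, t),
            "ribo": _pct(self.n_ribo, t),
            "rna_only": _pct(self.n_rna_only, t),
            "both": _pct(self.n_both, t),
            "ribo_only": _pct(self.n_ribo_only, t),
            "iclip_de": _pct(self.n_iclip_de, t),
            "iclip_rna": _pct(self.n_iclip_rna, it),
            "iclip_ribo": _pct(self.n_iclip_ribo, it),
            "iclip_rna_only": _pct(self.n_iclip_rna_only, it),
            "iclip_both": _pct(self.n_iclip_both, it),
            "iclip_ribo_only": _pct(self.n_iclip_ribo_only, it),
        }

    def as_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            ("DE genes", self.n_de_total, 100.0 if self.n_de_total else 0.0),
            ("RNASeq", self.n_rna, pct["rna"]),
            ("RiboSeq", self.n_ribo, pct["ribo"]),
            ("RNASeq only", self.n_rna_only, pct["rna_only"]),
            ("RNASeq and RiboSeq", self.n_both, pct["both"]),
            ("RiboSeq only", self.n_ribo_only, pct["ribo_only"]),
            ("DE and iCLIP", self.n_iclip_de, pct["iclip_de"]),
            ("DE and iCLIP in RNASeq", self.n_iclip_rna, pct["iclip_rna"]),
            ("DE and iCLIP in RiboSeq", self.n_iclip_ribo, pct["iclip_ribo"]),
            ("DE and iCLIP in RNASeq only", self.n_iclip_rna_only, pct["iclip_rna_only"]),
            ("DE and iCLIP in both", self.n_iclip_both, pct["iclip_both"]),
            ("DE and iCLIP in RiboSeq only", self.n_iclip_ribo_only, pct["iclip_ribo_only"]),
        ]
        return pd.DataFrame(rows, columns=["group", "n", "percent"])


def summarize_de_overlap(
    de_rna: DETable,
    de_ribo: DETable,
    iclip_targets: set[str],
    padj_threshold: float = 0.05,
) -> OverlapSummary:
    """Partition DE genes into RNA-only / both / Ribo-only, overall and within
    the iCLIP target set."""
    if not 0.0 < padj_threshold < 1.0:
        raise ValueError("padj_threshold must be in (0, 1)")
    rna = de_rna.significant(padj_threshold)
    ribo = de_ribo.significant(padj_threshold)
    union = rna | ribo

    def block(rna_s: set[str], ribo_s: set[str]) -> tuple[int, int, int, int, int, int]:
        u = rna_s | ribo_s
        both = rna_s & ribo_s
        return (len(u), len(rna_s), len(ribo_s),
                len(rna_s - ribo_s), len(both), len(ribo_s - rna_s))

    overall = block(rna, ribo)
    restricted = block(rna & iclip_targets, ribo & iclip_targets)
    return OverlapSummary(*overall, *restricted, empty=(len(union) == 0))


def compare_fold_changes(
    de_table: DETable,
    target_set: set[str],
    region_restricted_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of target vs non-target log2 fold changes.

    Uses the normal approximation with continuity correction, or the exact
    null enumeration when both groups have at most 8 untied observations.
    ``region_restricted_sets`` adds one comparison per binding-region subset
    (non-targets stay the complement of the full target set).
    """
    df = de_table.df
    nontarget_lfc = df.loc[~df["gene_id"].isin(target_set), "log2fc"].to_numpy()
    comparisons = {"all": target_set}
    if region_restricted_sets:
        comparisons.update(region_restricted_sets)
    rows = []
    for name, genes in comparisons.items():
        target_lfc = df.loc[df["gene_id"].isin(genes), "log2fc"].to_numpy()
        if len(target_lfc) == 0:
            raise ValueError(f"target group {name!r} is empty")
        if len(nontarget_lfc) == 0:
            raise ValueError("non-target group is empty")
        rows.append({
            "comparison": name,
            "n_target": len(target_lfc),
            "n_nontarget": len(nontarget_lfc),
            "rank_sum_p": rank_sum_test(target_lfc, nontarget_lfc),
            "median_target": float(np.median(target_lfc)),
            "median_nontarget": float(np.median(nontarget_lfc)),
        })
    return pd.DataFrame(rows)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value (continuity-corrected normal
    approximation; exact enumeration when both n <= 8 and there are no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # no separation at all
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def gene_set_response(
    gene_set: set[str],
    de_rna: DETable,
    de_ribo: DETable,
    padj_threshold: float = 0.05,
    iclip_targets: set[str] | None = None,
) -> pd.DataFrame:
    """Counts of increased/decreased genes of a gene set per modality, with
    the iCLIP-target member count of each group (the bracketed numbers of a
    gene-set response plot)."""
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    iclip_targets = iclip_targets or set()
    rows = []
    for table in (de_rna, de_ribo):
        df = table.df[table.df["gene_id"].isin(gene_set)]
        sig = df[df["padj"] < padj_threshold]
        up = set(sig.loc[sig["log2fc"] > 0, "gene_id"])
        down = set(sig.loc[sig["log2fc"] < 0, "gene_id"])
        rows.append({
            "modality": table.modality,
            "increased": len(up),
            "increased_iclip": len(up & iclip_targets),
            "decreased": len(down),
            "decreased_iclip": len(down & iclip_targets),
        })
    return pd.DataFrame(rows)
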