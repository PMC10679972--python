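"""DEG thresholding and directional Venn partitioning across contrasts.

A gene is differentially expressed when FDR < .05 and |log2 fold change|
> 1 (both strict).  The partition of two contrasts' DEG sets tracks
direction: a gene up in one contrast and down in the other is reported
in a separate discordant cell rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_adjust

__all__ = [
    "DEStat",
    "DEGSet",
    "VennPartition",
    "threshold_degs",
    "venn_partition",
    "partition_consistency",
    "simple_de_test",
    "read_de_table",
]

FDR_MAX = 0.05
MIN_ABS_LOG2FC = 1.0


@dataclass(frozen=True)
class DEStat:
    """Per-gene differential statistic; positive log2fc = up in the first group."""

    gene: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0 <= self.pvalue <= 1 and 0 <= self.fdr <= 1):
            raise ValueError(f"{self.gene}: p/fdr outside [0, 1]")


@dataclass
class DEGSet:
    """Directional DEG sets for one contrast."""

    contrast: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")

    @property
    def all(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class VennPartition:
    """Directional partition of two contrasts' DEG sets."""

    unique_a: DEGSet
    unique_b: DEGSet
    overlap_up: set[str]
    overlap_down: set[str]
    discordant: set[str]

    @property
    def overlap_total(self) -> int:
        return len(self.overlap_up) + len(self.overlap_down) + len(self.discordant)


def threshold_degs(
    stats: Sequence[DEStat],
    contrast: str = "",
    fdr_max: float = FDR_MAX,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> DEGSet:
    """Apply the DEG gates: FDR < fdr_max and |log2FC| > min_abs_log2fc (strict)."""
    genes = [s.gene for s in stats]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene(s): {dupes[:5]}")
    up = {s.gene for s in stats if s.fdr < fdr_max and s.log2fc > min_abs_log2fc}
    down = {s.gene for s in stats if s.fdr < fdr_max and s.log2fc < -min_abs_log2fc}
    return DEGSet(contrast=contrast, up=up, down=down)


def venn_partition(a: DEGSet, b: DEGSet) -> VennPartition:
    """Directional Venn partition of two DEG sets.

    Direction must be defined relative to the same reference group in
    both contrasts.  Totals satisfy |a| = |unique_a| + overlap_total and
    likewise for b.
    """
    shared = a.all & b.all
    overlap_up = a.up & b.up
    overlap_down = a.down & b.down
    discordant = shared - overlap_up - overlap_down
    unique_a = DEGSet(contrast=a.contrast, up=a.up - shared, down=a.down - shared)
    unique_b = DEGSet(contrast=b.contrast, up=b.up - shared, down=b.down - shared)
    return VennPartition(
        unique_a=unique_a,
        unique_b=unique_b,
        overlap_up=overlap_up,
        overlap_down=overlap_down,
        discordant=discordant,
    )


def partition_consistency(total: int, unique: int) -> int:
    """Overlap implied by printed totals: overlap = total - unique.

    Works for all-gene counts and per-direction counts alike; raises on
    the inconsistent case unique > total.
    """
    if unique > total:
        raise ValueError(f"unique ({unique}) exceeds total ({total})")
    return total - unique


def simple_de_test(
    counts: pd.DataFrame, groups: Sequence[str], pseudocount: float = 0.5
) -> list[DEStat]:
    """Rank-sum differential test on library-size-normalised counts.

    A deliberately simple stand-in for a full negative-binomial DE model:
    counts are scaled to the mean library size, a pseudocount added, the
    log2 FC taken between group means, p-values from the two-sided
    Wilcoxon rank-sum test and FDR from Benjamini-Hochberg.  ``counts``
    is genes x samples; ``groups`` labels the samples with exactly two
    levels, and log2fc is positive when the first-named level is higher.
    """
    groups = list(groups)
    if len(groups) != counts.shape[1]:
        raise ValueError("groups must label every sample column")
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    ga = [i for i, g in enumerate(groups) if g == levels[0]]
    gb = [i for i, g in enumerate(groups) if g == levels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    libsize = mat.sum(axis=0)
    norm = mat / libsize * libsize.mean() + pseudocount
    stats: list[DEStat] = []
    pvals = np.empty(mat.shape[0])
    l2fc = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        a, b = norm[i, ga], norm[i, gb]
        if mat[i].sum() == 0:
            pvals[i], l2fc[i] = 1.0, 0.0
            continue
        l2fc[i] = np.log2(a.mean() / b.mean())
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
        else:
            pvals[i] = _sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    fdr = bh_adjust(pvals)
    for i, gene in enumerate(counts.index):
        stats.append(
            DEStat(gene=str(gene), log2fc=float(l2fc[i]), pvalue=float(pvals[i]), fdr=float(fdr[i]))
        )
    return stats


def read_de_table(path: str | Path, contrast: str = "") -> list[DEStat]:
    """DE stat TSV: gene, log2fc, pvalue, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "log2fc", "pvalue", "fdr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    return [
        DEStat(
            gene=str(r.gene),
            log2fc=float(r.log2fc),
            pvalue=float(r.pvalue),
            fdr=float(r.fdr),
        )
        for r in df.itertuples()
    ]
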