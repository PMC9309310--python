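"""Developmental opsin expression: depth normalization and log heatmaps.

RNA-seq read counts per opsin gene across a developmental series (stages
tagged in day-degrees, dd) are made comparable by scaling every sample to
the sequencing depth of the shallowest sample, i.e. column j is multiplied
by min(depth) / depth_j. This preserves within-sample proportions exactly
and leaves every column sum equal to the minimum depth.

The heatmap matrix is log2(normalized count + pseudocount) by default; an
alternative mode expresses each stage as a log2 fold change against a
reference stage (the earliest, unless overridden).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "normalize_to_min_depth",
    "log_heatmap_matrix",
    "stage_mean",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass
class CountMatrix:
    """A gene x sample count table (genes as rows)."""

    counts: pd.DataFrame
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)


def normalize_to_min_depth(m: CountMatrix) -> CountMatrix:
    """Scale every sample to the depth of the lowest-read sample."""
    depths = m.depths()
    zero = depths[depths <= 0]
    if len(zero):
        raise ValueError(
            f"zero-depth sample(s): {', '.join(map(str, zero.index))}")
    scaled = m.counts * (depths.min() / depths)
    return CountMatrix(counts=scaled, normalized=True, meta=dict(m.meta))


def log_heatmap_matrix(m: CountMatrix, pseudocount: float = 1.0,
                       mode: str = "absolute",
                       reference_sample: str | None = None) -> pd.DataFrame:
    """Log2 matrix for heatmap display.

    ``mode="absolute"`` gives log2(count + pseudocount) per cell;
    ``mode="fold_change"`` gives log2((count + pc) / (count_ref + pc))
    against ``reference_sample`` (default: the first column, i.e. the
    earliest stage).
    """
    if not m.normalized:
        raise ValueError("normalize the count matrix before log transform")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    logged = np.log2(m.counts + pseudocount)
    if mode == "absolute":
        return logged
    if mode == "fold_change":
        ref = reference_sample or m.samples[0]
        if ref not in m.counts.columns:
            raise ValueError(f"reference sample {ref!r} not in matrix")
        return logged.sub(logged[ref], axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def stage_mean(replicate_counts: dict[str, CountMatrix]) -> CountMatrix:
    """Arithmetic mean of normalized replicate columns per stage.

    ``replicate_counts`` maps stage label -> CountMatrix whose columns are
    the replicates of that stage. All matrices must share the same genes.
    """
    if not replicate_counts:
        raise ValueError("no stages supplied")
    stages = list(replicate_counts)
    genes = replicate_counts[stages[0]].genes
    cols = {}
    for stage, m in replicate_counts.items():
        if m.genes != genes:
            raise ValueError(
                f"stage {stage!r}: gene set differs from other stages")
        cols[stage] = m.counts.mean(axis=1)
    out = pd.DataFrame(cols, index=genes)
    normalized = all(m.normalized for m in replicate_counts.values())
    return CountMatrix(counts=out, normalized=normalized)


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Genes as rows, samples as columns, header row of stage labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return CountMatrix(counts=df)


def write_counts_tsv(m: CountMatrix, path: str | Path,
                     header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        m.counts.to_csv(fh, sep="\t", index_label="gene")
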