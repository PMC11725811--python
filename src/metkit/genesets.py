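"""Differential-expression thresholding and gene-set overlap arithmetic.

The transcriptomic endpoint of the pipeline is set arithmetic on
differentially expressed genes (DEGs).  A gene is a DEG when
``|log2FC| > 0.5`` and ``lfcSE < 0.5`` and ``padj < 0.01`` (strict
inequalities; the fold-change threshold is applied to the magnitude since
both up- and downregulated genes are reported).  Downstream operations are
exact Venn partitions, overlap percentages in both raw and round-half-up
integer form, and the overlap of a curated hair-bundle/stereocilia gene
panel with the DEGs, split by direction of change.

Identifier normalization is trim + case-fold only; no ortholog or symbol
mapping is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "GeneSet",
    "DEGFilterResult",
    "OverlapReport",
    "PercentValue",
    "normalize_id",
    "filter_degs",
    "venn_partition",
    "overlap_percentage",
    "panel_overlap",
]

DEFAULT_THRESHOLDS = {
    "min_abs_log2fc": 0.5,
    "max_lfcse": 0.5,
    "max_padj": 0.01,
}

REQUIRED_COLUMNS = ("gene_id", "log2FC", "lfcSE", "padj")


def normalize_id(gene: str) -> str:
    return str(gene).strip().casefold()


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes) -> "GeneSet":
        return cls(label, frozenset(normalize_id(g) for g in genes))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return normalize_id(gene) in self.members


@dataclass(frozen=True)
class PercentValue:
    """A percentage kept in both raw and printed (integer) form."""

    raw: float

    @property
    def rounded(self) -> int:
        # round-half-up, the convention for printed integer percentages
        return int(math.floor(self.raw + 0.5))


@dataclass
class DEGFilterResult:
    genes: GeneSet
    up: GeneSet
    down: GeneSet
    n_missing_padj: int
    thresholds: dict[str, float]

    @property
    def directions(self) -> dict[str, str]:
        d = {g: "up" for g in self.up.members}
        d.update({g: "down" for g in self.down.members})
        return d


@dataclass
class OverlapReport:
    label_a: str
    label_b: str
    only_a: int
    intersection: int
    only_b: int
    pct_of_a: PercentValue
    pct_of_b: PercentValue
    intersection_up: int | None = None
    intersection_down: int | None = None
    members: frozenset[str] = field(default_factory=frozenset)

    @property
    def union(self) -> int:
        return self.only_a + self.intersection + self.only_b


def filter_degs(
    table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    label: str = "degs",
) -> DEGFilterResult:
    """Apply the DEG thresholds to a differential-expression table.

    Keeps rows with ``|log2FC| > min_abs_log2fc`` AND
    ``lfcSE < max_lfcse`` AND ``padj < max_padj`` (all strict).  Rows with
    missing padj are excluded and counted.  The sign of log2FC labels each
    kept gene up or down.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    n_missing_padj = int(table["padj"].isna().sum())
    t = table.dropna(subset=["padj"])
    keep = (
        (t["log2FC"].abs() > thr["min_abs_log2fc"])
        & (t["lfcSE"] < thr["max_lfcse"])
        & (t["padj"] < thr["max_padj"])
    )
    kept = t[keep]
    up = kept.loc[kept["log2FC"] > 0, "gene_id"]
    down = kept.loc[kept["log2FC"] < 0, "gene_id"]
    return DEGFilterResult(
        genes=GeneSet.from_iterable(label, kept["gene_id"]),
        up=GeneSet.from_iterable(f"{label}_up", up),
        down=GeneSet.from_iterable(f"{label}_down", down),
        n_missing_padj=n_missing_padj,
        thresholds=thr,
    )


def venn_partition(
    a: GeneSet,
    b: GeneSet,
    directions: dict[str, str] | None = None,
) -> OverlapReport:
    """Exact two-set partition (A\\B, A^B, B\\A) with overlap percentages.

    ``directions`` (gene -> "up"/"down", e.g. from
    :attr:`DEGFilterResult.directions`) adds a direction breakdown of the
    intersection.
    """
    inter = a.members & b.members
    only_a = len(a.members - b.members)
    only_b = len(b.members - a.members)
    up = down = None
    if directions is not None:
        norm = {normalize_id(g): d for g, d in directions.items()}
        up = sum(1 for g in inter if norm.get(g) == "up")
        down = sum(1 for g in inter if norm.get(g) == "down")
    pct_a = PercentValue(100.0 * len(inter) / len(a)) if len(a) else PercentValue(0.0)
    pct_b = PercentValue(100.0 * len(inter) / len(b)) if len(b) else PercentValue(0.0)
    return OverlapReport(a.label, b.label, only_a, len(inter), only_b,
                         pct_a, pct_b, up, down, frozenset(inter))


def overlap_percentage(numerator, denominator) -> PercentValue:
    """``100 * |A ^ B| / |B|`` as raw + round-half-up integer.

    ``numerator`` may be an int (a pre-computed intersection count) or a
    GeneSet to intersect with the denominator; ``denominator`` may be an
    int or a GeneSet.  An empty denominator is an error.
    """
    if isinstance(denominator, GeneSet):
        denom_n = len(denominator)
    else:
        denom_n = int(denominator)
    if denom_n <= 0:
        raise ValueError("empty denominator set")
    if isinstance(numerator, GeneSet):
        if not isinstance(denominator, GeneSet):
            raise ValueError("set numerator requires a set denominator")
        num_n = len(numerator.members & denominator.members)
    else:
        num_n = int(numerator)
    return PercentValue(100.0 * num_n / denom_n)


def panel_overlap(
    panel: GeneSet,
    degs: DEGFilterResult | GeneSet,
    directions: dict[str, str] | None = None,
    exclude: tuple[str, ...] = (),
) -> OverlapReport:
    """Overlap of a curated gene panel with the DEGs.

    ``exclude`` removes genes (e.g. the knocked-out gene itself) from the
    panel before counting, shrinking the denominator.  The report's
    ``pct_of_a`` is the fraction of the (post-exclusion) panel that is
    differentially expressed, with the up/down split when directions are
    available.
    """
    excl = {normalize_id(g) for g in exclude}
    panel_set = GeneSet(panel.label, panel.members - excl)
    if isinstance(degs, DEGFilterResult):
        if directions is None:
            directions = degs.directions
        degs = degs.genes
    return venn_partition(panel_set, degs, directions=directions)
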