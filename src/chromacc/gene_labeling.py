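"""Binary gene-level accessibility labels from peak/hotspot intervals.

A gene is called *open* when at least one peak shares at least one base
pair with its regulatory region — the union of a TSS-anchored promoter
window and the gene body (UTRs included) — and *closed* otherwise.  Peaks
are used strand-blind (DNase hotspots carry no strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

OPEN = "open"
CLOSED = "closed"

#: Default promoter window around the TSS. The extent is deliberately an
#: explicit, configurable parameter so users can match whatever annotation
#: tool defined their promoters.
DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 100


@dataclass(frozen=True)
class RegulatoryRegion:
    """Promoter window plus gene body of one gene."""

    gene_id: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"{self.gene_id}: regulatory region must be non-empty")
        chroms = {iv.chrom for iv in self.intervals}
        if len(chroms) != 1:
            raise ValueError(f"{self.gene_id}: intervals span multiple chromosomes")


@dataclass
class AccessibilityLabels:
    """Binary open/closed assignment for a set of genes.

    ``labels`` is a boolean Series indexed by gene_id (True = open);
    ``source`` records provenance (hotspot-derived | predicted |
    gold-standard | simulated-truth).
    """

    labels: pd.Series
    source: str

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate gene ids in labels")
        self.labels = self.labels.astype(bool)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def open_genes(self) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels])

    @property
    def closed_genes(self) -> frozenset[str]:
        return frozenset(self.labels.index[~self.labels])

    def label(self, gene_id: str) -> str:
        return OPEN if bool(self.labels.loc[gene_id]) else CLOSED

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.labels.index,
                "label": [OPEN if v else CLOSED for v in self.labels.values],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "hotspot-derived") -> "AccessibilityLabels":
        df = pd.read_csv(path, sep="\t")
        bad = set(df["label"]) - {OPEN, CLOSED}
        if bad:
            raise ValueError(f"{path}: unknown label(s) {sorted(bad)}")
        series = pd.Series(
            (df["label"] == OPEN).values, index=df["gene_id"].astype(str).values
        )
        return cls(labels=series, source=source)


def promoter_window(
    gene: GeneRecord,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> GenomicInterval | None:
    """TSS-anchored promoter window, strand-aware, clipped at position 0.

    Returns None when the window is empty (upstream == downstream == 0):
    a zero-length promoter is treated as absent.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.start - upstream, gene.start + downstream
    else:
        # For a - strand gene the TSS is the 3'-most coordinate; upstream
        # extends toward larger coordinates.
        start, end = gene.end - downstream, gene.end + upstream
    start = max(start, 0)
    if end <= start:
        return None
    return GenomicInterval(gene.chrom, start, end, name=f"{gene.gene_id}:promoter")


def regulatory_region(
    gene: GeneRecord,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> RegulatoryRegion:
    """Promoter window (if non-empty) plus the gene body."""
    intervals: list[GenomicInterval] = [gene.body()]
    prom = promoter_window(gene, upstream, downstream)
    if prom is not None:
        intervals.append(prom)
    return RegulatoryRegion(gene_id=gene.gene_id, intervals=tuple(intervals))


def _peak_trees(peaks: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def open_gene_set(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> frozenset[str]:
    """Genes whose regulatory region shares >= 1 bp with any peak."""
    trees = _peak_trees(peaks)
    hits: set[str] = set()
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        for iv in regulatory_region(gene, upstream, downstream).intervals:
            if tree.overlaps(iv.start, iv.end):
                hits.add(gene.gene_id)
                break
    return frozenset(hits)


def assign_accessibility(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    source: str = "hotspot-derived",
) -> AccessibilityLabels:
    """Label every gene open/closed from overlap with the peak set.

    An empty peak list is valid (every gene closed); an empty gene list is
    an error.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    opened = open_gene_set(peaks, genes, upstream, downstream)
    series = pd.Series(
        [g.gene_id in opened for g in genes],
        index=[g.gene_id for g in genes],
    )
    return AccessibilityLabels(labels=series, source=source)
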