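"""Coupled expression/accessibility simulators for end-to-end fixtures.

The generator emulates the statistical structure the classifier assumes:
per cell type, gene-level FPKM is drawn from a class-conditional lognormal
mixture with a point mass at zero for silent genes, and the true
open/closed state follows a (sharp, by default) logistic link of
expression, P(open | e) = logistic((e - theta) * steepness), optionally
corrupted by label flips.  DNase hotspots are then placed inside open
genes' bodies (missed with a small probability) and spuriously inside
some closed genes, so errors concentrate at low expression, as they do in
real data.

Hotspots and simulated gold-standard evidence are placed at least
:data:`PLACEMENT_MARGIN` bp inside the owning gene's body; because that
margin exceeds the default promoter extent, a peak never leaks into a
neighboring gene's regulatory region and zero-noise samples round-trip
exactly through peak-overlap labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .gene_labeling import AccessibilityLabels
from .io_formats import (
    ChromHmmSegment,
    GeneRecord,
    GenomicInterval,
    write_bed,
    write_expression_table,
    write_gene_annotation,
)
from .peakcaller_optimization import PeakCallRun

#: Minimum distance (bp) between a placed feature and the owning gene's
#: ends; larger than the default 1000 bp promoter upstream extent so
#: features never overlap a neighbor's regulatory region.
PLACEMENT_MARGIN = 1200

_GENE_TYPES = ("protein_coding", "lincRNA", "pseudogene")
_GENE_TYPE_P = (0.7, 0.2, 0.1)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated cohort.

    Expression is in FPKM.  ``open_expr_lognormal``/``closed_expr_lognormal``
    are (mu, sigma) of the underlying normal of log-FPKM for the two
    expressed classes; ``link_theta`` (FPKM) and ``link_steepness``
    (1/FPKM) parameterize the logistic expression->accessibility link.
    """

    n_genes: int = 20_000
    n_chromosomes: int = 4
    gene_length_bp: tuple[int, int] = (3_000, 10_000)
    frac_silent: float = 0.3
    open_expr_lognormal: tuple[float, float] = (1.0, 1.0)
    closed_expr_lognormal: tuple[float, float] = (-3.0, 1.0)
    link_theta: float = 0.5
    link_steepness: float = 50.0
    label_noise: float = 0.02
    peak_len_bp: int = 300
    fn_peak_rate: float = 0.02
    fp_peak_rate: float = 0.02
    chrom_length_bp: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_silent", "label_noise", "fn_peak_rate", "fp_peak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.open_expr_lognormal[1] <= 0 or self.closed_expr_lognormal[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
        if self.link_steepness <= 0:
            raise ValueError("link_steepness must be > 0")
        if self.gene_length_bp[0] < 2 * PLACEMENT_MARGIN + self.peak_len_bp:
            raise ValueError(
                "minimum gene length must exceed 2*PLACEMENT_MARGIN + peak_len_bp "
                "to keep placed features inside gene bodies"
            )
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be >= 1")


@dataclass
class SyntheticSample:
    """One simulated cell type: annotation, expression, truth, hotspots."""

    sample_id: str
    genes: list[GeneRecord]
    expression: pd.Series
    truth: AccessibilityLabels
    hotspots: list[GenomicInterval]


def _make_genes(params: SimulationParams, rng: np.random.Generator) -> list[GeneRecord]:
    lo, hi = params.gene_length_bp
    per_chrom = np.array_split(np.arange(params.n_genes), params.n_chromosomes)
    genes: list[GeneRecord] = []
    for c, idx in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos = 1500
        for i in idx:
            length = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(2500, 6001))
            start, end = pos, pos + length
            if params.chrom_length_bp is not None and end > params.chrom_length_bp:
                raise ValueError(
                    f"genes do not fit on {chrom} of length {params.chrom_length_bp}"
                )
            genes.append(
                GeneRecord(
                    gene_id=f"g{i:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    gene_type=str(rng.choice(_GENE_TYPES, p=_GENE_TYPE_P)),
                    gc_content=float(rng.uniform(0.3, 0.7)),
                )
            )
            pos = end + gap
    return genes


def _central_interval(
    gene: GeneRecord, length: int, rng: np.random.Generator
) -> GenomicInterval:
    lo = gene.start + PLACEMENT_MARGIN
    hi = gene.end - PLACEMENT_MARGIN - length
    start = int(rng.integers(lo, hi + 1)) if hi > lo else (gene.start + gene.end - length) // 2
    return GenomicInterval(gene.chrom, start, start + length)


def simulate_cell_type(
    params: SimulationParams,
    seed: int | None = None,
    genes: list[GeneRecord] | None = None,
    sample_id: str = "ct0",
) -> SyntheticSample:
    """Draw one cell type: expression, true labels and hotspot intervals."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if genes is None:
        genes = _make_genes(params, rng)
    n = len(genes)

    silent = rng.random(n) < params.frac_silent
    from_open_class = rng.random(n) < 0.5
    mu_o, sd_o = params.open_expr_lognormal
    mu_c, sd_c = params.closed_expr_lognormal
    e = np.where(
        from_open_class,
        rng.lognormal(mean=mu_o, sigma=sd_o, size=n),
        rng.lognormal(mean=mu_c, sigma=sd_c, size=n),
    )
    e[silent] = 0.0

    p_open = expit((e - params.link_theta) * params.link_steepness)
    truth = rng.random(n) < p_open
    truth ^= rng.random(n) < params.label_noise

    hotspots: list[GenomicInterval] = []
    for gene, is_open in zip(genes, truth):
        if is_open:
            if rng.random() >= params.fn_peak_rate:
                hotspots.append(_central_interval(gene, params.peak_len_bp, rng))
        elif rng.random() < params.fp_peak_rate:
            hotspots.append(_central_interval(gene, params.peak_len_bp, rng))

    gene_ids = [g.gene_id for g in genes]
    expression = pd.Series(e, index=gene_ids, name="fpkm")
    labels = AccessibilityLabels(
        labels=pd.Series(truth, index=gene_ids), source="simulated-truth"
    )
    return SyntheticSample(
        sample_id=sample_id,
        genes=genes,
        expression=expression,
        truth=labels,
        hotspots=hotspots,
    )


def simulate_training_set(
    params: SimulationParams, n_samples: int, seed: int | None = None
) -> list[SyntheticSample]:
    """Independent cell types sharing one gene annotation."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(n_samples + 1)
    genes = _make_genes(params, np.random.default_rng(children[0]))
    samples = []
    for i in range(n_samples):
        sample_seed = int(np.random.default_rng(children[i + 1]).integers(0, 2**31 - 1))
        samples.append(
            simulate_cell_type(
                params, seed=sample_seed, genes=genes, sample_id=f"ct{i:02d}"
            )
        )
    return samples


def simulate_gold_standard(
    sample: SyntheticSample,
    params: SimulationParams,
    seed: int | None = None,
    n_experiments: int = 3,
    coverage: float = 1.0,
    conflict_rate: float = 0.0,
    segment_len_bp: int = 500,
) -> tuple[list[list[GenomicInterval]], list[ChromHmmSegment]]:
    """TFBS pseudo-experiments for open genes, heterochromatin segments for
    closed genes.

    With ``coverage < 1`` only that fraction of each truth class receives
    evidence, so the derived gold standard is a subset of the truth;
    ``conflict_rate`` additionally places heterochromatin segments over
    some TFBS-covered open genes to exercise conflict handling.
    """
    if not 0.0 <= coverage <= 1.0 or not 0.0 <= conflict_rate <= 1.0:
        raise ValueError("coverage and conflict_rate must be in [0, 1]")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tfbs: list[list[GenomicInterval]] = [[] for _ in range(n_experiments)]
    segments: list[ChromHmmSegment] = []
    open_ids = sample.truth.open_genes
    for gene in sample.genes:
        if gene.gene_id in open_ids:
            if rng.random() < coverage:
                exp = int(rng.integers(0, n_experiments))
                tfbs[exp].append(_central_interval(gene, params.peak_len_bp, rng))
                if rng.random() < conflict_rate:
                    segments.append(_het_segment(gene, segment_len_bp, rng))
        elif rng.random() < coverage:
            segments.append(_het_segment(gene, segment_len_bp, rng))
    return tfbs, segments


def _het_segment(
    gene: GeneRecord, length: int, rng: np.random.Generator
) -> ChromHmmSegment:
    if rng.random() < 0.8:
        state, marks = "Het", frozenset({"H3K9me3"})
    else:
        state, marks = "ZNF/Rpts", frozenset({"H3K36me3", "H3K4me3", "H3K9me3"})
    return ChromHmmSegment(
        interval=_central_interval(gene, length, rng), state=state, marks=marks
    )


def simulate_peak_caller_runs(
    sample: SyntheticSample,
    miss_rates: Sequence[float],
    fp_rates: Sequence[float],
    seed: int | None = None,
    caller: str = "sim",
) -> list[PeakCallRun]:
    """Degraded copies of the sample's hotspots, one run per rate pair.

    Run i drops each true hotspot with probability ``miss_rates[i]`` and
    adds a spurious peak inside each truth-closed gene with probability
    ``fp_rates[i]``; its pseudo-threshold is the index i.
    """
    if len(miss_rates) != len(fp_rates):
        raise ValueError("miss_rates and fp_rates must have equal length")
    for v in list(miss_rates) + list(fp_rates):
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    closed_ids = sample.truth.closed_genes
    closed_genes = [g for g in sample.genes if g.gene_id in closed_ids]
    runs: list[PeakCallRun] = []
    for i, (miss, fp) in enumerate(zip(miss_rates, fp_rates)):
        peaks = [h for h in sample.hotspots if rng.random() >= miss]
        for gene in closed_genes:
            if rng.random() < fp:
                peaks.append(_central_interval(gene, 300, rng))
        runs.append(
            PeakCallRun(caller=caller, threshold=float(i), peaks=tuple(peaks))
        )
    return runs


def write_sample_dir(
    sample: SyntheticSample, out_dir: str | Path, write_annotation: bool = True
) -> None:
    """Write a sample as on-disk fixtures (GTF + TSV + BED)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_annotation:
        write_gene_annotation(sample.genes, out / "genes.gtf")
    write_expression_table(sample.expression, out / "expression.tsv")
    sample.truth.to_tsv(out / "labels.tsv")
    write_bed(sample.hotspots, out / "hotspots.bed")
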