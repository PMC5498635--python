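"""Gold-standard construction, F1 evaluation and validation procedures.

The gold standard couples two independent lines of evidence: genes whose
regulatory region overlaps at least one transcription-factor ChIP-seq peak
(in any of the available experiments) form the accessible reference set —
TF binding requires nucleosome-depleted DNA, and intragenic enhancers act
as alternative promoters, so intragenic binding counts too.  Genes
overlapping heterochromatin-typical ChromHMM segments (states annotated to
H3K9me3 alone, or to the H3K36me3+H3K4me3+H3K9me3 combination typical of
ZNF genes/repeats) form the inaccessible set.  Genes claimed by both lines
of evidence are moved to a conflict set and excluded.

Accessible genes are the positive class throughout; precision is
TP/(TP+FP), recall TP/(TP+FN) and F1 their harmonic mean,
F1 = 2 * precision * recall / (precision + recall), with 0/0 -> 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gene_labeling import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    AccessibilityLabels,
    open_gene_set,
)
from .hierarchical_model import HierarchicalModel, TrainingConfig, fit_hierarchical, predict
from .io_formats import ChromHmmSegment, GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

#: Mark sets defining heterochromatin-typical ChromHMM states.
HET_MARK_SETS = (
    frozenset({"H3K9me3"}),
    frozenset({"H3K36me3", "H3K4me3", "H3K9me3"}),
)


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint accessible/inaccessible reference gene sets."""

    accessible: frozenset[str]
    inaccessible: frozenset[str]
    conflicts: frozenset[str] = frozenset()
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.accessible & self.inaccessible:
            raise ValueError("accessible and inaccessible sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.accessible | self.inaccessible


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    expression_cutoff: float = 0.0
    undefined: bool = False


# ---------------------------------------------------------------------------
# Gold standard construction
# ---------------------------------------------------------------------------


def build_accessible_set(
    tfbs_peak_sets: Sequence[Sequence[GenomicInterval]],
    genes: Sequence[GeneRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> frozenset[str]:
    """Genes overlapped by >= 1 TFBS peak in >= 1 experiment (union)."""
    if not tfbs_peak_sets:
        raise ValueError("need at least one TFBS peak set")
    accessible: set[str] = set()
    for peaks in tfbs_peak_sets:
        accessible |= open_gene_set(peaks, genes, upstream, downstream)
    return frozenset(accessible)


def build_inaccessible_set(
    segments: Sequence[ChromHmmSegment],
    genes: Sequence[GeneRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    superset_match: bool = False,
) -> frozenset[str]:
    """Genes overlapping heterochromatin-typical ChromHMM segments.

    A segment qualifies when its mark set equals one of
    :data:`HET_MARK_SETS`; with ``superset_match=True`` a superset of
    either criterion also qualifies.
    """
    if superset_match:
        het = [
            s.interval
            for s in segments
            if any(s.marks >= crit for crit in HET_MARK_SETS)
        ]
    else:
        het = [s.interval for s in segments if s.marks in HET_MARK_SETS]
    return frozenset(open_gene_set(het, genes, upstream, downstream))


def build_gold_standard(
    accessible: Iterable[str],
    inaccessible: Iterable[str],
    provenance: str = "",
) -> GoldStandard:
    """Combine the two reference sets, quarantining genes claimed by both."""
    acc, inacc = frozenset(accessible), frozenset(inaccessible)
    if not acc and not inacc:
        raise ValueError("both reference sets are empty")
    conflicts = acc & inacc
    if conflicts:
        logger.info("%d gene(s) in both reference sets moved to conflicts", len(conflicts))
    return GoldStandard(
        accessible=acc - conflicts,
        inaccessible=inacc - conflicts,
        conflicts=conflicts,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def confusion(predicted: AccessibilityLabels, gold: GoldStandard) -> ConfusionCounts:
    """Tally predictions against the gold standard (open = positive class).

    Every gold gene must carry a prediction; silently dropping uncovered
    gold genes would inflate the scores.
    """
    covered = set(predicted.labels.index)
    missing = gold.genes - covered
    if missing == gold.genes:
        raise ValueError("no gold-standard gene is covered by the predictions")
    if missing:
        raise ValueError(
            f"{len(missing)} gold-standard gene(s) lack predictions "
            f"(e.g. {sorted(missing)[:3]})"
        )
    open_pred = predicted.open_genes
    tp = len(gold.accessible & open_pred)
    fn = len(gold.accessible) - tp
    fp = len(gold.inaccessible & open_pred)
    tn = len(gold.inaccessible) - fp
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def f1_score(counts: ConfusionCounts, expression_cutoff: float = 0.0) -> EvalResult:
    """Precision, recall and their harmonic mean, with the 0/0 -> 0 convention."""
    precision = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    recall = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalResult(
        precision=precision,
        recall=recall,
        f1=f1,
        counts=counts,
        expression_cutoff=expression_cutoff,
    )


def _restrict_gold(gold: GoldStandard, keep: set[str]) -> GoldStandard:
    return GoldStandard(
        accessible=gold.accessible & keep,
        inaccessible=gold.inaccessible & keep,
        conflicts=gold.conflicts & keep,
        provenance=gold.provenance,
    )


def f1_threshold_sweep(
    predicted: AccessibilityLabels,
    gold: GoldStandard,
    expression: pd.Series,
    cutoffs: Sequence[float],
) -> list[EvalResult]:
    """F1 after restricting to gold genes expressed above each cutoff.

    A cutoff of 0 means *all* genes (no restriction); any other cutoff c
    keeps genes with FPKM strictly greater than c.  A cutoff excluding
    every gold gene yields an ``undefined``-flagged result rather than an
    exception.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    fpkm = expression.reindex(list(gold.genes), fill_value=0.0)
    results: list[EvalResult] = []
    for c in cutoffs:
        if c == 0:
            keep = set(gold.genes)
        else:
            keep = set(fpkm.index[fpkm > c])
        sub = _restrict_gold(gold, keep)
        if not sub.genes:
            results.append(
                EvalResult(
                    precision=float("nan"),
                    recall=float("nan"),
                    f1=float("nan"),
                    counts=ConfusionCounts(0, 0, 0, 0),
                    expression_cutoff=float(c),
                    undefined=True,
                )
            )
            continue
        results.append(f1_score(confusion(predicted, sub), expression_cutoff=float(c)))
    return results


# ---------------------------------------------------------------------------
# Misclassification profiles
# ---------------------------------------------------------------------------

DEFAULT_EXPRESSION_BIN_EDGES = (0.0, 0.1, 0.5, 1.0, 5.0, 25.0, float("inf"))
DEFAULT_GC_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.05, 0.1), 2))


def misclassification_profile(
    predicted: AccessibilityLabels,
    gold: GoldStandard,
    genes: Sequence[GeneRecord],
    expression: pd.Series,
    attribute: str,
    expression_bin_edges: Sequence[float] = DEFAULT_EXPRESSION_BIN_EDGES,
    gc_bin_edges: Sequence[float] = DEFAULT_GC_BIN_EDGES,
) -> pd.DataFrame:
    """Where do errors fall, per category of a gene attribute?

    For each category of ``attribute`` (gc, gene_type, chromosome or
    expression_bin) the fraction of that category's gold genes that are
    misclassified is reported, plus each category's share of all errors.
    """
    if attribute not in ("gc", "gene_type", "chromosome", "expression_bin"):
        raise ValueError(f"unknown attribute {attribute!r}")
    by_id = {g.gene_id: g for g in genes}
    gold_genes = sorted(gold.genes)
    missing = [g for g in gold_genes if g not in by_id]
    if missing:
        raise ValueError(f"gold gene(s) missing from annotation: {missing[:3]}")

    open_pred = predicted.open_genes
    covered = set(predicted.labels.index)
    uncovered = set(gold_genes) - covered
    if uncovered:
        raise ValueError(f"{len(uncovered)} gold gene(s) lack predictions")
    mis = np.array(
        [
            (g in gold.accessible) != (g in open_pred)
            for g in gold_genes
        ]
    )

    if attribute == "chromosome":
        cats = pd.Series([by_id[g].chrom for g in gold_genes], index=gold_genes)
    elif attribute == "gene_type":
        cats = pd.Series([by_id[g].gene_type for g in gold_genes], index=gold_genes)
    elif attribute == "gc":
        gc = [by_id[g].gc_content for g in gold_genes]
        if any(v is None for v in gc):
            raise ValueError("attribute 'gc': gc_content missing for some gold genes")
        cats = pd.cut(pd.Series(gc, index=gold_genes), bins=list(gc_bin_edges)).astype(str)
    else:  # expression_bin
        fpkm = expression.reindex(gold_genes, fill_value=0.0)
        cats = pd.cut(
            fpkm, bins=list(expression_bin_edges), right=False, include_lowest=True
        ).astype(str)

    df = pd.DataFrame({"category": cats, "misclassified": mis})
    grouped = df.groupby("category", observed=True)["misclassified"].agg(["size", "sum"])
    grouped.columns = ["n_gold", "n_misclassified"]
    grouped["frac_misclassified"] = grouped["n_misclassified"] / grouped["n_gold"]
    total_mis = int(grouped["n_misclassified"].sum())
    grouped["error_share"] = (
        grouped["n_misclassified"] / total_mis if total_mis else 0.0
    )
    return grouped


# ---------------------------------------------------------------------------
# Validation procedures
# ---------------------------------------------------------------------------


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)


def loo_validation(
    training_samples: Sequence[tuple[pd.Series, AccessibilityLabels]],
    config: TrainingConfig,
    partition_by: str = "cell_type",
    genes: Sequence[GeneRecord] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Leave-one-out concordance with the full model.

    ``partition_by="cell_type"``: each fold drops one training sample,
    and the fold model's prediction scores on the held-out sample's
    expression are correlated with the full model's.

    ``partition_by="chromosome"``: each fold drops the genes of one
    chromosome from training; scores on the held-out chromosome's genes
    (concatenated across all samples' profiles) are correlated.
    """
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(training_samples))]
    full = fit_hierarchical(training_samples, config, sample_ids=sample_ids)
    out: dict[str, float] = {}

    if partition_by == "cell_type":
        if len(training_samples) < 3:
            raise ValueError("cell_type partitioning needs >= 3 samples")
        for i, (expr, _) in enumerate(training_samples):
            rest = [s for j, s in enumerate(training_samples) if j != i]
            rest_ids = [s for j, s in enumerate(sample_ids) if j != i]
            fold = fit_hierarchical(rest, config, sample_ids=rest_ids)
            full_scores, _ = predict(full, expr)
            fold_scores, _ = predict(fold, expr)
            out[sample_ids[i]] = pearson_correlation(
                full_scores.values, fold_scores.values
            )
        return out

    if partition_by == "chromosome":
        if genes is None:
            raise ValueError("chromosome partitioning needs the gene annotation")
        chrom_of = {g.gene_id: g.chrom for g in genes}
        chroms = sorted({g.chrom for g in genes})
        if len(chroms) < 2:
            raise ValueError("chromosome partitioning needs >= 2 chromosomes")
        for chrom in chroms:
            held = {g for g, c in chrom_of.items() if c == chrom}
            rest_samples = []
            for expr, labels in training_samples:
                keep = [g for g in expr.index if g not in held]
                rest_samples.append(
                    (
                        expr.loc[keep],
                        AccessibilityLabels(
                            labels=labels.labels.loc[
                                labels.labels.index.intersection(keep)
                            ],
                            source=labels.source,
                        ),
                    )
                )
            fold = fit_hierarchical(rest_samples, config, sample_ids=sample_ids)
            full_parts, fold_parts = [], []
            for expr, _ in training_samples:
                held_genes = [g for g in expr.index if g in held]
                if not held_genes:
                    continue
                full_parts.append(predict(full, expr.loc[held_genes])[0].values)
                fold_parts.append(predict(fold, expr.loc[held_genes])[0].values)
            out[chrom] = pearson_correlation(
                np.concatenate(full_parts), np.concatenate(fold_parts)
            )
        return out

    raise ValueError(f"unknown partition_by {partition_by!r}")


def replicate_concordance(
    model: HierarchicalModel, expr_rep1: pd.Series, expr_rep2: pd.Series
) -> float:
    """Pearson correlation of prediction scores across two expression replicates."""
    shared = expr_rep1.index.intersection(expr_rep2.index)
    if len(shared) < 3:
        raise ValueError("replicates must share >= 3 genes")
    s1, _ = predict(model, expr_rep1.loc[shared])
    s2, _ = predict(model, expr_rep2.loc[shared])
    return pearson_correlation(s1.values, s2.values)
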