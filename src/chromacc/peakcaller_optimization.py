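"""Rank peak-caller parameter settings against model predictions.

Peak callers expose an FDR (or z-score) threshold whose optimal value is
not known a priori.  Because the model's accessibility predictions are a
reliable stand-in for the accessible class, a run's quality can be scored
without any gold standard as the *recall of its called peaks against the
predictions*: among genes predicted open and expressed above a small FPKM
floor (0.01 by default), the fraction that the run's peaks also call open.
Settings ranked by this recall reproduce the ranking obtained by F1
against a true gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gene_labeling import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    AccessibilityLabels,
    open_gene_set,
)
from .gold_standard_eval import pearson_correlation
from .io_formats import GeneRecord, GenomicInterval


@dataclass(frozen=True)
class PeakCallRun:
    """One peak caller's output at one threshold setting."""

    caller: str
    threshold: float
    peaks: tuple[GenomicInterval, ...]
    replicate_id: str | None = None

    @property
    def key(self) -> tuple:
        return (self.caller, self.threshold, self.replicate_id)


@dataclass(frozen=True)
class RankedRun:
    run: PeakCallRun
    recall: float
    rank: int
    tied: bool = False


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("need >= 3 points")
        if self.adjusted_r_squared > self.r_squared + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed R^2")


def recall_vs_predictions(
    run: PeakCallRun,
    genes: Sequence[GeneRecord],
    predicted: AccessibilityLabels,
    expression: pd.Series,
    min_fpkm: float = 0.01,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> float:
    """Recall of a run's called peaks against the model's predictions.

    The reference positives are the genes predicted open with FPKM above
    ``min_fpkm``; the run's observed positives are the genes its peaks
    label open.  Returns TP / (TP + FN) over the reference set.
    """
    fpkm = expression.reindex(predicted.labels.index, fill_value=0.0)
    real_pos = predicted.open_genes & set(fpkm.index[fpkm > min_fpkm])
    if not real_pos:
        raise ValueError(f"no predicted-open gene expressed above {min_fpkm} FPKM")
    observed_open = open_gene_set(run.peaks, genes, upstream, downstream)
    tp = len(real_pos & observed_open)
    return tp / len(real_pos)


def rank_settings(
    runs: Sequence[PeakCallRun],
    genes: Sequence[GeneRecord],
    predicted: AccessibilityLabels,
    expression: pd.Series,
    min_fpkm: float = 0.01,
    stringent_high: bool | Mapping[str, bool] = False,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[RankedRun]:
    """Order runs by recall against predictions, best first.

    Ties are broken by threshold stringency (more stringent first) and
    flagged.  ``stringent_high`` says whether a *larger* threshold is more
    stringent for a caller (True for z-score thresholds, False for FDR);
    it may be a single bool or a per-caller mapping.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")

    def _stringency(run: PeakCallRun) -> float:
        high = (
            stringent_high.get(run.caller, False)
            if isinstance(stringent_high, Mapping)
            else stringent_high
        )
        return -run.threshold if high else run.threshold

    recalls = [
        recall_vs_predictions(
            r, genes, predicted, expression, min_fpkm, upstream, downstream
        )
        for r in runs
    ]
    order = sorted(
        range(len(runs)), key=lambda i: (-recalls[i], _stringency(runs[i]))
    )
    ranked: list[RankedRun] = []
    for pos, i in enumerate(order):
        tied = any(
            j != i and recalls[j] == recalls[i] for j in order
        )
        ranked.append(RankedRun(run=runs[i], recall=recalls[i], rank=pos + 1, tied=tied))
    return ranked


def regress_f1_on_recall(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """Ordinary least squares of F1 on recall across (recall, f1) points.

    Adjusted R^2 follows 1 - (1 - R^2)(n - 1)/(n - p - 1) with p = 1.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.std(x) == 0:
        raise ValueError("recall values are collinear (zero variance)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        adjusted_r_squared=float(model.rsquared_adj),
        n_points=len(points),
    )


def compare_rankings(
    rank_a: Sequence[PeakCallRun | RankedRun | tuple],
    rank_b: Sequence[PeakCallRun | RankedRun | tuple],
) -> float:
    """Pearson correlation of the two orderings' integer rank vectors."""

    def _key(item):
        if isinstance(item, RankedRun):
            return item.run.key
        if isinstance(item, PeakCallRun):
            return item.key
        return item

    keys_a = [_key(x) for x in rank_a]
    keys_b = [_key(x) for x in rank_b]
    if set(keys_a) != set(keys_b) or len(keys_a) != len(keys_b):
        raise ValueError("rankings cover different setting universes")
    pos_a = {k: i for i, k in enumerate(keys_a)}
    pos_b = {k: i for i, k in enumerate(keys_b)}
    universe = sorted(pos_a, key=lambda k: pos_a[k])
    ra = [pos_a[k] for k in universe]
    rb = [pos_b[k] for k in universe]
    return pearson_correlation(ra, rb)
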