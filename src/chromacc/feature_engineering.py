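"""Per-gene predictor vectors for the bottom-layer trees.

Each gene contributes three predictors: its raw FPKM value e_i and the
Mahalanobis distances of e_i to the empirical expression distributions of
the accessible and of the inaccessible training genes,

    d(e_i) = (e_i - mu_X) . S_X^{-1} . (e_i - mu_X)'

with mu_X the sample mean and S_X the sample covariance of class X (a
scalar variance in this 1-D setting; the distance is the squared
standardized deviation, no square root is taken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_labeling import AccessibilityLabels

FEATURE_COLUMNS = ("e", "d_open", "d_closed")


class DegenerateClassError(ValueError):
    """A class has too few members or zero expression variance."""


@dataclass(frozen=True)
class ClassDistributionStats:
    """Sample mean/variance of one class's FPKM values."""

    class_label: str
    mu: float
    var: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateClassError(
                f"class {self.class_label!r}: need >= 2 members, got {self.n}"
            )
        if not self.var > 0:
            raise DegenerateClassError(
                f"class {self.class_label!r}: zero expression variance"
            )


def fit_class_distributions(
    expression: pd.Series, labels: AccessibilityLabels
) -> tuple[ClassDistributionStats, ClassDistributionStats]:
    """Fit (open, closed) expression distributions from labeled genes.

    Mean and variance use the n-1 denominator.  A class with fewer than two
    members or all-identical expression raises
    :class:`DegenerateClassError` rather than being epsilon-inflated, so
    pathological labelings surface loudly.
    """
    common = expression.index.intersection(labels.labels.index)
    values = expression.loc[common].to_numpy(dtype=float)
    is_open = labels.labels.loc[common].to_numpy(dtype=bool)
    out = []
    for class_label, mask in (("open", is_open), ("closed", ~is_open)):
        cls = values[mask]
        if cls.size < 2:
            raise DegenerateClassError(
                f"class {class_label!r}: need >= 2 members, got {cls.size}"
            )
        var = float(np.var(cls, ddof=1))
        if not var > 0:
            raise DegenerateClassError(f"class {class_label!r}: zero expression variance")
        out.append(
            ClassDistributionStats(
                class_label=class_label, mu=float(np.mean(cls)), var=var, n=int(cls.size)
            )
        )
    return out[0], out[1]


def mahalanobis(e: float | np.ndarray, stats: ClassDistributionStats) -> float | np.ndarray:
    """Squared standardized deviation of e from the class distribution."""
    d = np.square(np.asarray(e, dtype=float) - stats.mu) / stats.var
    if np.ndim(e) == 0:
        return float(d)
    return d


def build_feature_matrix(
    expression: pd.Series,
    stats_open: ClassDistributionStats,
    stats_closed: ClassDistributionStats,
) -> pd.DataFrame:
    """One row per gene, in the input profile's order: [e, d_open, d_closed].

    The matrix is a deterministic function of (expression, stats): genes
    with equal FPKM get identical rows, which is what makes the whole
    classifier a deterministic function of expression.
    """
    e = expression.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "e": e,
            "d_open": mahalanobis(e, stats_open),
            "d_closed": mahalanobis(e, stats_closed),
        },
        index=expression.index,
    )
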