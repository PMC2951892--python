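"""Replicate-aware normalization and statistical comparison of predictions
against measured mutant expression.

Expression tables are grouped by condition (wildtype, single knockouts,
double knockout, ...), rescaled gene-wise by the wildtype replicate mean,
and compared to model predictions with per-gene one-sample two-sided
t-tests (df = n_replicates - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

WILDTYPE = "wildtype"


class NormalizationError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """Replicate expression matrices keyed by condition label.

    conditions maps label -> DataFrame (genes x replicates) indexed by
    gene id; knockout_annotation maps condition -> set of knocked-out gene
    ids (empty for wildtype).
    """

    gene_ids: list[str]
    conditions: dict[str, pd.DataFrame]
    knockout_annotation: dict[str, set] = field(default_factory=dict)
    rescaled: bool = False

    def __post_init__(self) -> None:
        if WILDTYPE not in self.conditions:
            raise ValueError(f"dataset must contain a {WILDTYPE!r} condition")
        for label, mat in self.conditions.items():
            if list(mat.index) != list(self.gene_ids):
                raise ValueError(f"condition {label!r} gene index mismatch")
            if mat.shape[1] < 2:
                raise ValueError(f"condition {label!r} has < 2 replicates")

    def condition_mean(self, label: str) -> pd.Series:
        return self.conditions[label].mean(axis=1)

    def condition_sd(self, label: str) -> pd.Series:
        return self.conditions[label].std(axis=1, ddof=1)


def rescale_by_wildtype(data: ExpressionDataset) -> ExpressionDataset:
    """Divide every replicate of every condition gene-wise by the wildtype
    replicate mean, so rescaled wildtype means are exactly 1."""
    if data.rescaled:
        raise NormalizationError("dataset is already rescaled")
    wt_mean = data.condition_mean(WILDTYPE)
    bad = [g for g, v in wt_mean.items() if not (v > 0)]
    if bad:
        raise NormalizationError(
            f"non-positive wildtype mean for genes: {bad[:10]}"
            + (" ..." if len(bad) > 10 else "")
        )
    conditions = {
        label: mat.div(wt_mean, axis=0) for label, mat in data.conditions.items()
    }
    return replace(data, conditions=conditions, rescaled=True)


def zero_knocked_out_levels(data: ExpressionDataset) -> ExpressionDataset:
    """Replace the measured level of each condition's knocked-out genes by 0
    in all replicates (measured signal of a knocked-out gene is assumed to be
    a non-functional analog)."""
    conditions = {}
    for label, mat in data.conditions.items():
        genes = data.knockout_annotation.get(label, set())
        missing = set(genes) - set(data.gene_ids)
        if missing:
            raise AnnotationError(
                f"condition {label!r} annotates absent genes: {sorted(missing)}"
            )
        mat = mat.copy()
        if genes:
            mat.loc[sorted(genes)] = 0.0
        conditions[label] = mat
    return replace(data, conditions=conditions)


@dataclass
class ComparisonResult:
    gene: str
    predicted: float
    observed_mean: float
    observed_sd: float
    n_rep: int
    t_stat: float  # NaN when degenerate
    df: int
    rejected: bool
    degenerate: bool = False


def ttest_vs_prediction(
    replicates, predicted: float, alpha: float = 0.05, gene: str = ""
) -> ComparisonResult:
    """One-sample two-sided t-test of replicate measurements against a
    predicted mean; df = n - 1.

    With zero replicate spread the statistic is undefined: the comparison is
    flagged degenerate and rejection is decided by exact equality.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n = int(x.size)
    df = n - 1
    if np.all(x == x[0]):
        # identical replicates: the statistic is undefined; decide by exact
        # equality of the (common) observed value and the prediction
        mean = float(x[0])
        return ComparisonResult(
            gene=gene, predicted=float(predicted), observed_mean=mean,
            observed_sd=0.0, n_rep=n, t_stat=float("nan"), df=df,
            rejected=mean != float(predicted), degenerate=True,
        )
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    t = (mean - float(predicted)) / (sd / np.sqrt(n))
    crit = float(stats.t.ppf(1 - alpha / 2, df))
    return ComparisonResult(
        gene=gene, predicted=float(predicted), observed_mean=mean,
        observed_sd=sd, n_rep=n, t_stat=float(t), df=df,
        rejected=bool(abs(t) > crit),
    )


def compare_double_knockout(
    data: ExpressionDataset,
    ees,
    ko_pair,
    condition: str | None = None,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> dict:
    """Compare EES predictions for a double knockout against its replicates.

    Predicts the free internal genes (both knockout genes clamped to 0) and
    all external genes, then t-tests each gene's replicates against its
    prediction.  Returns the per-gene table, the rejected fraction, and
    histogram bins of the t statistic.
    """
    from eesnet.ees_core import predict_mutant

    a, b = ko_pair
    if not data.rescaled:
        raise ValueError("dataset must be rescaled before comparison")
    if a not in ees.internal or b not in ees.internal:
        raise ValueError(f"knockout pair {ko_pair} must both be internal genes")
    if condition is None:
        matches = [
            lbl
            for lbl, genes in data.knockout_annotation.items()
            if set(genes) == {a, b}
        ]
        if not matches:
            raise ValueError(f"no condition annotated as double knockout of {ko_pair}")
        condition = matches[0]
    if condition not in data.conditions:
        raise ValueError(f"condition {condition!r} absent from dataset")

    predicted = predict_mutant(ees, {a: 0.0, b: 0.0})
    pred = pd.Series(predicted, index=ees.gene_ids).reindex(data.gene_ids)
    mat = data.conditions[condition]

    rows = []
    for g in data.gene_ids:
        if g in (a, b):
            continue  # clamped genes are inputs, not predictions
        rows.append(ttest_vs_prediction(mat.loc[g].to_numpy(), pred[g],
                                        alpha=alpha, gene=g))
    table = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "internal": [r.gene in set(ees.internal) for r in rows],
            "predicted": [r.predicted for r in rows],
            "observed_mean": [r.observed_mean for r in rows],
            "observed_sd": [r.observed_sd for r in rows],
            "n_rep": [r.n_rep for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "df": [r.df for r in rows],
            "rejected": [r.rejected for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    ).set_index("gene")

    finite_t = table["t_stat"].to_numpy()
    finite_t = finite_t[np.isfinite(finite_t)]
    counts, edges = np.histogram(finite_t, bins=n_bins)
    return {
        "table": table,
        "condition": condition,
        "rejected_fraction": float(table["rejected"].mean()),
        "n_tested": int(len(table)),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def max_normalized_deviation(data: ExpressionDataset) -> pd.Series:
    """Per gene, the largest |mutant mean - wildtype mean| over all mutant
    conditions, normalized by the wildtype replicate standard deviation.

    Genes with zero wildtype sd are flagged with +inf (degenerate) unless no
    mutant deviates, in which case the value is 0.
    """
    if not data.rescaled:
        raise ValueError("dataset must be rescaled first")
    wt_mean = data.condition_mean(WILDTYPE)
    wt_sd = data.condition_sd(WILDTYPE)
    dev = pd.Series(0.0, index=pd.Index(data.gene_ids, name="gene"))
    for label in data.conditions:
        if label == WILDTYPE:
            continue
        diff = (data.condition_mean(label) - wt_mean).abs()
        dev = np.maximum(dev, diff)
    zero_sd = wt_sd == 0
    out = dev / wt_sd.where(~zero_sd, other=1.0)
    out[zero_sd & (dev > 0)] = np.inf
    out.name = "max_normalized_deviation"
    return out
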