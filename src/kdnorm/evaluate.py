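"""Differential-expression scoring, ROC/AUC, and fold-change compression.

Evaluation is ranking-based: genes are scored either by the absolute log2
fold change between the two groups or by the pooled-variance two-sample
t-test p-value, and ROC curves are drawn against the designed truth.  A
probe set that is constant across all arrays carries no information for the
t-test, so its p-value is set to 1 (and its t statistic left undefined)
rather than dropped.

Fold-change accuracy is summarized by the *compression slope*: the OLS
slope of observed on designed log2 fold change over genes with designed
fold change > 1.  Slope 1 means no compression; smaller means the
normalization shrank true effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

from .core import LOG2, ExpressionMatrix

TRUTH_COLUMNS = ["gene_id", "designed_log2_fc", "is_de", "is_empty"]


def make_truth(gene_ids, designed_log2_fc, is_de, is_empty) -> pd.DataFrame:
    """Assemble and validate a design-truth table."""
    truth = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "designed_log2_fc": np.asarray(designed_log2_fc, dtype=float),
            "is_de": np.asarray(is_de, dtype=bool),
            "is_empty": np.asarray(is_empty, dtype=bool),
        }
    )
    validate_truth(truth)
    return truth


def validate_truth(truth: pd.DataFrame) -> None:
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth table is missing columns {missing}")
    if truth["gene_id"].duplicated().any():
        dup = truth.loc[truth["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in truth table")
    de_mismatch = truth["is_de"] != (truth["designed_log2_fc"] != 0)
    if de_mismatch.any():
        g = truth.loc[de_mismatch, "gene_id"].iloc[0]
        raise ValueError(
            f"gene {g!r}: is_de must hold exactly when designed_log2_fc != 0"
        )
    if (truth["is_empty"] & truth["is_de"]).any():
        g = truth.loc[truth["is_empty"] & truth["is_de"], "gene_id"].iloc[0]
        raise ValueError(f"empty gene {g!r} cannot be differentially expressed")


def gene_scores(
    m: ExpressionMatrix,
    group_a,
    group_b,
    with_t: bool = True,
) -> pd.DataFrame:
    """Per-gene log2 fold change and pooled-variance two-sample t-test.

    log2_fc = mean(group_a) − mean(group_b).  The t statistic uses the
    pooled variance with n_a + n_b − 2 degrees of freedom and a two-sided
    p-value.  Genes whose pooled variance is zero (identical values within
    each group) get p = 1 and an undefined (NaN) t statistic.
    """
    if m.scale != LOG2:
        raise ValueError("gene_scores expects a log2-scale matrix")
    ia = [m.array_index(a) for a in group_a]
    ib = [m.array_index(b) for b in group_b]
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    va = m.values[:, ia]
    vb = m.values[:, ib]
    n_a, n_b = va.shape[1], vb.shape[1]
    log2_fc = va.mean(axis=1) - vb.mean(axis=1)
    out = pd.DataFrame({"gene_id": m.probe_ids, "log2_fc": log2_fc})
    if with_t:
        if n_a < 2 or n_b < 2:
            raise ValueError(
                "t-test needs >= 2 arrays per group; pass with_t=False for "
                "fold change only"
            )
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * va.var(axis=1, ddof=1) + (n_b - 1) * vb.var(axis=1, ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2_fc / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        zero_var = sp2 == 0.0
        t[zero_var] = np.nan
        p[zero_var] = 1.0
        out["t_stat"] = t
        out["p_value"] = p
    return out


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_from_scores(score, is_de) -> RocResult:
    """ROC of a higher-is-more-DE score against boolean truth labels.

    Tied scores share a threshold; the AUC is the trapezoid area, which for
    tied blocks equals the Mann–Whitney U statistic with half-credit ties.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(is_de, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one DE and one non-DE gene")
    fpr, tpr, _ = metrics.roc_curve(labels, score, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(metrics.auc(fpr, tpr)))


def roc_curve(
    scores: pd.DataFrame,
    truth: pd.DataFrame,
    criterion: str = "fc",
    include_empty: bool = False,
) -> RocResult:
    """ROC against the designed truth, ranking by |log2 fc| or by p-value.

    ``criterion="fc"`` ranks by decreasing |log2_fc|; ``"t"`` by increasing
    p-value.  Empty probe sets are excluded unless ``include_empty``.
    """
    validate_truth(truth)
    merged = truth.merge(scores, on="gene_id", how="inner")
    if len(merged) != len(scores):
        raise ValueError(
            f"{len(scores) - len(merged)} scored genes are absent from the truth table"
        )
    if not include_empty:
        merged = merged[~merged["is_empty"]]
    if criterion == "fc":
        score = np.abs(merged["log2_fc"].to_numpy())
    elif criterion == "t":
        if "p_value" not in merged:
            raise ValueError("t-test ranking requires p_value scores")
        score = -merged["p_value"].to_numpy()
    else:
        raise ValueError(f"unknown criterion {criterion!r} (expected 'fc' or 't')")
    return roc_from_scores(score, merged["is_de"].to_numpy())


def compression_slope(
    scores: pd.DataFrame,
    truth: pd.DataFrame,
    include_empty: bool = False,
) -> tuple[float, float]:
    """OLS slope/intercept of observed on designed log2 fold change.

    Restricted to genes with designed (raw) fold change > 1, i.e. designed
    log2 fc > 0; empty probe sets are excluded.  Returns (slope, intercept).
    """
    validate_truth(truth)
    merged = truth.merge(scores, on="gene_id", how="inner")
    if not include_empty:
        merged = merged[~merged["is_empty"]]
    sel = merged[merged["designed_log2_fc"] > 0]
    if len(sel) < 2:
        raise ValueError("need >= 2 genes with designed fold change > 1")
    x = sel["designed_log2_fc"].to_numpy()
    y = sel["log2_fc"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all designed fold changes equal")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def null_ma_bias(
    m: ExpressionMatrix,
    truth: pd.DataFrame,
    include_empty: bool = False,
) -> float:
    """Worst per-array median M of the null genes after normalization.

    For each array, M is the difference against the common reference of the
    (normalized) matrix; the median over null (non-DE, non-empty) genes
    measures how far that array's null cluster sits from the zero line.
    Returns the maximum |median| over arrays — 0 for a perfectly centred
    normalization.
    """
    from .core import common_reference  # local import avoids a cycle at import time

    validate_truth(truth)
    order = {g: i for i, g in enumerate(truth["gene_id"])}
    rows = np.asarray([order[p] for p in m.probe_ids], dtype=int)
    null = (~truth["is_de"]).to_numpy()[rows]
    if not include_empty:
        null &= (~truth["is_empty"]).to_numpy()[rows]
    if not null.any():
        raise ValueError("no null genes to assess")
    ref = common_reference(m)
    biases = [
        np.median(m.values[null, j] - ref[null]) for j in range(m.n_arrays)
    ]
    return float(max(abs(b) for b in biases))


def null_bias(
    scores: pd.DataFrame,
    truth: pd.DataFrame,
    include_empty: bool = False,
) -> float:
    """Median observed log2 fold change of the null (non-DE, non-empty) genes.

    After a successful normalization this is ~0; global methods applied to
    asymmetric data leave a systematic offset here.
    """
    validate_truth(truth)
    merged = truth.merge(scores, on="gene_id", how="inner")
    mask = ~merged["is_de"]
    if not include_empty:
        mask &= ~merged["is_empty"]
    if not mask.any():
        raise ValueError("no null genes to assess")
    return float(merged.loc[mask, "log2_fc"].median())
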