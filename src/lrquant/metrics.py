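"""Accuracy metrics for estimated vs. reference transcript abundances.

Rank correlations (Spearman, Kendall tau-b) are computed on the raw counts;
Pearson and Lin's concordance correlation coefficient (CCC) on the
log(1 + x) scale, where quantification accuracy is conventionally judged.
Error metrics: RMSE, NRMSE (RMSE normalised by the mean reference value), and
MARD with the bounded absolute relative difference

    ARD = |x - y| / (x + y),   defined as 0 when x = y = 0,

so each transcript contributes a value in [0, 1].  The ARD convention is a
deliberate choice (the quantity has no single standard definition); a
different denominator changes MARD's scale.

Expressed-transcript detection is scored with a precision-recall curve using
the estimated abundance itself as the ranking score.  InfRV (inferential
relative variance) summarises the uncertainty of an estimate across
inferential replicates: ``max(sigma^2 - mu, 0) / (mu + 5) + 0.01``; the
pseudocount of 5 stabilises low-mean transcripts and the additive 0.01 keeps
the value positive for log transformation.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    spearman: float
    pearson_log1p: float
    ccc: float
    kendall: float
    rmse: float
    nrmse: float
    mard: float
    auc_pr: float
    average_precision: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float
    average_precision: float


def _safe_corr(fn, x, y) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(fn(x, y).statistic)


def concordance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's CCC with population moments; nan for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    vx, vy = x.var(), y.var()
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def absolute_relative_difference(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|x - y| / (x + y), with 0 where both are 0; bounded in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        ard = np.abs(x - y) / denom
    return np.where(denom == 0, 0.0, ard)


def precision_recall(estimated: np.ndarray, truth_expressed: np.ndarray) -> PRResult:
    """PR curve over descending abundance threshold; AP = sum (R_k - R_{k-1}) P_k."""
    labels = np.asarray(truth_expressed, dtype=bool)
    scores = np.asarray(estimated, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("precision-recall needs at least one positive and one negative label")
    precision, recall, thresholds = sklearn.metrics.precision_recall_curve(labels, scores)
    auc = float(sklearn.metrics.auc(recall, precision))
    ap = float(sklearn.metrics.average_precision_score(labels, scores))
    return PRResult(
        precision=precision, recall=recall, thresholds=thresholds, auc=auc, average_precision=ap
    )


def infrv(mu, sigma2):
    """Inferential relative variance: ``max(sigma^2 - mu, 0) / (mu + 5) + 0.01``."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(mu < 0) or np.any(sigma2 < 0):
        raise ValueError("mean and variance must be non-negative")
    out = np.maximum(sigma2 - mu, 0.0) / (mu + 5.0) + 0.01
    return float(out) if out.ndim == 0 else out


def compute_metrics(
    estimated, truth, *, log_scale_linear: bool = True
) -> MetricReport:
    """Full metric panel comparing estimated vs. reference counts.

    ``log_scale_linear`` keeps Pearson and CCC on the log(1+x) scale (the
    conventional pairing); set False for raw-scale variants.  Undefined
    quantities (zero-variance correlations, single-class PR) are reported as
    NaN rather than raised.
    """
    x = np.asarray(estimated, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("estimated and truth must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two transcripts to compare")
    lx, ly = (np.log1p(x), np.log1p(y)) if log_scale_linear else (x, y)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    nrmse = rmse / y.mean() if y.mean() > 0 else float("nan")
    expressed = y > 0
    if expressed.any() and not expressed.all():
        pr = precision_recall(x, expressed)
        auc, ap = pr.auc, pr.average_precision
    else:
        auc = ap = float("nan")
    return MetricReport(
        spearman=_safe_corr(scipy.stats.spearmanr, x, y),
        pearson_log1p=_safe_corr(scipy.stats.pearsonr, lx, ly),
        ccc=concordance_correlation(lx, ly),
        kendall=_safe_corr(scipy.stats.kendalltau, x, y),
        rmse=rmse,
        nrmse=float(nrmse),
        mard=float(absolute_relative_difference(x, y).mean()),
        auc_pr=auc,
        average_precision=ap,
    )


def evaluate_files(
    est_path: str | Path,
    truth_path: str | Path,
    est_column: str = "num_reads",
    truth_column: str = "true_count",
) -> MetricReport:
    """Compare two TSVs keyed by ``tname`` (inner join; unmatched names logged)."""
    est = pd.read_csv(est_path, sep="\t")
    truth = pd.read_csv(truth_path, sep="\t")
    for frame, col, path in ((est, est_column, est_path), (truth, truth_column, truth_path)):
        if "tname" not in frame.columns or col not in frame.columns:
            raise ValueError(f"{path} must have columns 'tname' and {col!r}")
    merged = est[["tname", est_column]].merge(
        truth[["tname", truth_column]], on="tname", how="inner"
    )
    unmatched = len(est) + len(truth) - 2 * len(merged)
    if unmatched:
        logger.warning("%d transcript names present in only one of the two files", unmatched)
    if len(merged) < 2:
        raise ValueError("fewer than two transcripts shared between the files")
    return compute_metrics(merged[est_column].to_numpy(), merged[truth_column].to_numpy())
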