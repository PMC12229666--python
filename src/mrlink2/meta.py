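"""Inverse-variance meta-analysis, heterogeneity, and benchmark metrics."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io import MRResult


@dataclass
class MetaResult:
    """Fixed-effect combination of per-region causal estimates."""

    alpha_bar: float
    se_bar: float
    p: float
    q_stat: float
    k: int


def _usable(results: Sequence[MRResult]):
    est = [
        (r.alpha_hat, r.se_alpha)
        for r in results
        if np.isfinite(r.alpha_hat) and np.isfinite(r.se_alpha) and r.se_alpha > 0
    ]
    return np.array([e[0] for e in est]), np.array([e[1] for e in est])


def meta_analyze(results: Sequence[MRResult]) -> MetaResult:
    """Weighted mean of regional estimates with weights ``se**-2``.

    ``alpha_bar = sum(a_r / se_r^2) / sum(se_r^-2)`` and
    ``se_bar = 1 / sqrt(sum(se_r^-2))``, the standard fixed-effect form; the
    P value is two-sided normal. With a single region the meta result equals
    the regional one exactly. Cochran's Q is attached whenever k >= 2.
    """
    alpha, se = _usable(results)
    if alpha.size == 0:
        raise ValueError("no regions with finite estimate and standard error")
    w = se**-2.0
    alpha_bar = float(np.sum(w * alpha) / np.sum(w))
    se_bar = float(np.sum(w) ** -0.5)
    p = float(max(2.0 * sps.norm.sf(abs(alpha_bar) / se_bar), np.nextafter(0, 1)))
    q = float(np.sum(((alpha - alpha_bar) / se) ** 2)) if alpha.size >= 2 else np.nan
    return MetaResult(alpha_bar=alpha_bar, se_bar=se_bar, p=p, q_stat=q,
                      k=int(alpha.size))


def cochran_q(results: Sequence[MRResult], meta: MetaResult | None = None) -> float:
    """Heterogeneity: sum of squared Z-score deviations from the pooled mean.

    ``Q = sum_r ((a_r - alpha_bar) / se_r)^2``, approximately chi-square with
    k-1 degrees of freedom under homogeneity. Requires k >= 2.
    """
    alpha, se = _usable(results)
    if alpha.size < 2:
        raise ValueError("Cochran's Q requires at least two regions")
    if meta is None:
        meta = meta_analyze(results)
    return float(np.sum(((alpha - meta.alpha_bar) / se) ** 2))


def detection_rate(p_values, threshold: float = 0.05) -> float:
    """Fraction of P values strictly below ``threshold``.

    Doubles as the type-I error rate under null scenarios and as power under
    causal ones.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite P values")
    return float(np.mean(p < threshold))


def auc_from_pvalues(p_null, p_causal) -> float:
    """Rank-based (Mann-Whitney) AUC separating causal from null simulations.

    Smaller P values count as more causal; ties contribute half. Invariant
    to any strictly monotone transform of the P values.
    """
    p_null = np.asarray(p_null, dtype=float)
    p_causal = np.asarray(p_causal, dtype=float)
    if p_null.size == 0 or p_causal.size == 0:
        raise ValueError("both P value sets must be non-empty")
    u = sps.mannwhitneyu(p_null, p_causal, alternative="two-sided").statistic
    return float(u / (p_null.size * p_causal.size))


def precision_recall(calls, truth) -> tuple[float, float]:
    """Precision and recall of significance calls against binary truth.

    Precision is NaN (flagged undefined) when nothing is called positive.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth are not aligned")
    tp = int(np.sum(calls & truth))
    called = int(calls.sum())
    positives = int(truth.sum())
    precision = tp / called if called else float("nan")
    recall = tp / positives if positives else float("nan")
    return precision, recall
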