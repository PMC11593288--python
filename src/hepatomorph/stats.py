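"""Trend and diagnostic statistics for ordinal fibrosis staging.

* Jonckheere–Terpstra test for a monotone trend of a feature across ordered
  stage groups (exact enumeration, Monte-Carlo permutation, or the
  tie-corrected normal approximation).
* AUROC with Youden-index operating points (sensitivity, specificity, F1)
  for dichotomized stage endpoints such as >=F3 or F4.
* Confusion-matrix reconstruction from printed sensitivity/specificity and
  class sizes, for auditing published operating points.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .shapes import FEATURE_COLUMNS

__all__ = [
    "TrendTestResult",
    "ConfusionCounts",
    "DiagnosticResult",
    "jonckheere_terpstra",
    "roc_auc",
    "confusion_from_rates",
    "f1_from_confusion",
    "stage_feature_table",
    "EXACT_N_LIMIT",
]

#: largest pooled sample size for which the exact permutation null is fully
#: enumerated under method="auto"
EXACT_N_LIMIT = 12

#: additional budget on the number of distinct arrangements (the multinomial
#: coefficient) before "auto" falls back to the normal approximation
EXACT_MAX_ARRANGEMENTS = 20_000

_MC_RESAMPLES = 100_000


@dataclass(frozen=True)
class TrendTestResult:
    jt_statistic: float
    z: float
    p_value: float
    method: str  # exact_permutation | monte_carlo_permutation | normal_approx
    tie_corrected: bool
    alternative: str


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float
    specificity: float
    f1: float
    auroc: float
    cutoff: float
    orientation: str  # high_positive | low_positive


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra

def _jt_statistic(groups: list[np.ndarray]) -> float:
    """Sum of pairwise Mann–Whitney counts over ordered group pairs (ties 1/2)."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            jt += (a < b).sum() + 0.5 * (a == b).sum()
    return float(jt)


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float, bool]:
    """Null mean and tie-corrected variance of the JT statistic."""
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    has_ties = bool((t > 1).any())

    mean = (n * n - (ns ** 2).sum()) / 4.0
    # Hollander & Wolfe tie-corrected null variance
    a = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    )
    b = (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    c = (ns * (ns - 1)).sum() * (t * (t - 1)).sum()
    var = a / 72.0
    if n > 2:
        var += b / (36.0 * n * (n - 1) * (n - 2))
    var += c / (8.0 * n * (n - 1))
    return mean, var, has_ties


def _perm_pvalue(
    stats_null: np.ndarray, observed: float, alternative: str, exact: bool
) -> float:
    eps = 1e-9
    m = len(stats_null)
    add = 0 if exact else 1  # include the observed arrangement for MC
    ge = ((stats_null >= observed - eps).sum() + add) / (m + add)
    le = ((stats_null <= observed + eps).sum() + add) / (m + add)
    if alternative == "increasing":
        return ge
    if alternative == "decreasing":
        return le
    return min(1.0, 2.0 * min(ge, le))


def jonckheere_terpstra(
    groups,
    alternative: str = "two_sided",
    method: str = "auto",
    seed: int = 0,
) -> TrendTestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    Parameters
    ----------
    groups : sequence of sequences
        Observations per group, in the hypothesized order (e.g. stage
        F0..F4).  All groups must be non-empty.
    alternative : {"two_sided", "increasing", "decreasing"}
    method : {"auto", "exact", "monte_carlo", "normal"}
        "auto" enumerates the full permutation null when the pooled sample
        size is at most ``EXACT_N_LIMIT``, otherwise uses the tie-corrected
        normal approximation.  "monte_carlo" draws 100 000 seeded
        permutations.
    seed : int
        Used by the Monte-Carlo method only.

    Returns
    -------
    TrendTestResult
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("two_sided", "increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")

    sizes = [len(g) for g in groups]
    n = sum(sizes)
    jt = _jt_statistic(groups)
    mean, var, has_ties = _jt_null_moments(groups)
    z = 0.0 if var <= 0 else (jt - mean) / math.sqrt(var)

    if method == "auto":
        n_arrangements = math.factorial(n)
        for size in sizes:
            n_arrangements //= math.factorial(size)
        method = (
            "exact"
            if n <= EXACT_N_LIMIT and n_arrangements <= EXACT_MAX_ARRANGEMENTS
            else "normal"
        )

    if method == "exact":
        pooled = np.concatenate(groups)
        null = np.array(
            [_jt_statistic(arr) for arr in _enumerate_partitions(pooled, sizes)]
        )
        p = _perm_pvalue(null, jt, alternative, exact=True)
        used = "exact_permutation"
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        bounds = np.cumsum(sizes)[:-1]
        null = np.empty(_MC_RESAMPLES)
        for k in range(_MC_RESAMPLES):
            perm = rng.permutation(pooled)
            null[k] = _jt_statistic(np.split(perm, bounds))
        p = _perm_pvalue(null, jt, alternative, exact=False)
        used = "monte_carlo_permutation"
    elif method == "normal":
        if var <= 0:
            p = 1.0
        elif alternative == "increasing":
            p = float(norm.sf(z))
        elif alternative == "decreasing":
            p = float(norm.cdf(z))
        else:
            p = float(2.0 * norm.sf(abs(z)))
        used = "normal_approx"
    else:
        raise ValueError(f"unknown method {method!r}")

    return TrendTestResult(
        jt_statistic=jt,
        z=float(z),
        p_value=float(min(1.0, p)),
        method=used,
        tie_corrected=has_ties,
        alternative=alternative,
    )


def _enumerate_partitions(pooled: np.ndarray, sizes: list[int]):
    """Yield every distinct assignment of pooled positions into ordered groups."""
    idx = tuple(range(len(pooled)))

    def rec(remaining: tuple, k: int):
        if k == len(sizes) - 1:
            yield [np.asarray(remaining)]
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, k + 1):
                yield [np.asarray(combo)] + tail

    for assignment in rec(idx, 0):
        yield [pooled[a] for a in assignment]


# ---------------------------------------------------------------------------
# ROC / AUROC

def roc_auc(values, labels, orientation: str = "auto") -> DiagnosticResult:
    """AUROC and a Youden-index operating point for a binary endpoint.

    AUROC is the pairwise concordance probability (ties count 1/2),
    computed by the rank-sum identity.  With ``orientation="auto"`` the
    feature is flipped when low values indicate the positive class (e.g. a
    thin lobe indicating advanced fibrosis), so the reported AUROC is always
    >= 0.5.  The cutoff maximizes Youden's J = sensitivity + specificity − 1
    over the observed values; sensitivity, specificity and F1 are reported
    at that cutoff.

    Parameters
    ----------
    values : sequence of float
    labels : sequence of bool
        True for the positive class; both classes must be present.
    orientation : {"auto", "high_positive", "low_positive"}
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def _auc(v):
        r = rankdata(v)
        return (r[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    if orientation not in ("auto", "high_positive", "low_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        orientation = "high_positive" if _auc(values) >= 0.5 else "low_positive"

    work = values if orientation == "high_positive" else -values
    auc = float(_auc(work))

    cutoffs = np.unique(work)
    best = None
    for t in cutoffs:
        call = work >= t
        tp = int((call & labels).sum())
        fp = int((call & ~labels).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec, tp, fp, fn)
    _, t, sens, spec, tp, fp, fn = best
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (tp + fp + fn) else float("nan")
    cutoff = float(t if orientation == "high_positive" else -t)
    return DiagnosticResult(
        sensitivity=float(sens),
        specificity=float(spec),
        f1=float(f1),
        auroc=auc,
        cutoff=cutoff,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Worked-example reconstruction

def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Rebuild integer confusion counts from printed rates and class sizes.

    ``TP = round(sensitivity * n_pos)`` and ``TN = round(specificity *
    n_neg)``; a warning is emitted when the printed rate is not integer-
    consistent with the class size (rounding error above 0.01).
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    for name, raw, rounded in (
        ("sensitivity", sensitivity * n_pos, tp),
        ("specificity", specificity * n_neg, tn),
    ):
        if abs(raw - rounded) > 0.01 * max(1.0, raw):
            warnings.warn(
                f"{name} is not integer-consistent with the class size "
                f"({raw:.3f} vs {rounded})",
                stacklevel=2,
            )
    return ConfusionCounts(TP=tp, FP=n_neg - tn, TN=tn, FN=n_pos - tp)


def f1_from_confusion(counts: ConfusionCounts) -> float:
    """F1 = 2·TP / (2·TP + FP + FN)."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        raise ValueError("undefined F1: TP = FP = FN = 0")
    return 2.0 * counts.TP / denom


# ---------------------------------------------------------------------------
# Feature-by-stage report

def stage_feature_table(
    features: pd.DataFrame,
    stages,
    alternative: str = "two_sided",
    method: str = "auto",
) -> pd.DataFrame:
    """One Jonckheere–Terpstra trend test per morphometric feature.

    Parameters
    ----------
    features : DataFrame
        One row per subject with the 16 feature columns (see
        :data:`hepatomorph.shapes.FEATURE_COLUMNS`).
    stages : sequence of int
        Ordinal fibrosis stage per subject (0–4).

    Returns
    -------
    DataFrame with columns ``feature`` and ``p`` in the canonical feature
    order.  Roundness is included even though published stage-trend tables
    commonly omit it.
    """
    stages = np.asarray(stages)
    if len(stages) != len(features):
        raise ValueError("stages and features must have equal length")
    present = np.unique(stages)
    if len(present) < 2:
        raise ValueError("need at least 2 distinct stages")
    rows = []
    for col in FEATURE_COLUMNS:
        if col not in features.columns:
            raise ValueError(f"missing feature column {col!r}")
        vals = features[col].to_numpy(dtype=float)
        groups = [vals[stages == s] for s in present]
        res = jonckheere_terpstra(groups, alternative=alternative, method=method)
        rows.append({"feature": col, "p": round(res.p_value, 3)})
    return pd.DataFrame(rows)
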