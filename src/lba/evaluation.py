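"""Accuracy, model-comparison, reliability, and information statistics.

Accuracy is the Pearson correlation between observed and out-of-fold
predicted scores. Two models of the *same* outcome are compared with a
paired t-test on per-participant prediction errors; models of *different*
outcomes with a paired bootstrap over participants, comparing the overlap
of the two accuracy distributions. Rating-scale reliability (inter-item
mean, corrected item-total mean, Cronbach's alpha) bounds the accuracy a
language-based model can be expected to reach (attenuation ceiling), and
the diversity index 2^H measures how much information a response format
carries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import PredictionResult, RatingScaleData
from .errors import (
    AlignmentError,
    InvalidComparisonError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "pearson_r",
    "ComparisonResult",
    "compare_same_outcome",
    "compare_bootstrap",
    "ReliabilityReport",
    "inter_item_mean",
    "corrected_item_total_mean",
    "cronbach_alpha",
    "reliability_report",
    "reliability_ceiling",
    "DiversityReport",
    "diversity_index",
    "word_count_stats",
    "interpret_r",
]


# ---------------------------------------------------------------------------
# Correlation


def pearson_r(a, b) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p (t transform, N-2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise AlignmentError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise InvalidInputError("need at least 3 observations for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Model comparison


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a significance test between two prediction models."""

    method: str  # "paired_error_t" | "bootstrap_overlap"
    statistic: float
    p_value: float
    model_names: tuple[str, str]
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError(f"p_value {self.p_value} outside [0, 1]")


_ERROR_TRANSFORMS = {
    "absolute": np.abs,
    "raw": lambda e: e,
    "squared": np.square,
}


def compare_same_outcome(
    res_a: PredictionResult,
    res_b: PredictionResult,
    error_transform: str = "absolute",
) -> ComparisonResult:
    """Paired t-test on per-participant prediction errors of the same outcome.

    Errors e = y - yhat are transformed per participant (default: absolute
    value, so that the test discriminates error *magnitude*; ``raw`` and
    ``squared`` are available) and compared with a paired-sample t-test.
    """
    if error_transform not in _ERROR_TRANSFORMS:
        raise InvalidParameterError(f"unknown error_transform {error_transform!r}")
    if res_a.n != res_b.n or not np.allclose(res_a.y_observed, res_b.y_observed):
        raise InvalidComparisonError(
            "models predict different outcomes; use compare_bootstrap for that comparison"
        )
    f = _ERROR_TRANSFORMS[error_transform]
    ea = f(res_a.y_observed - res_a.y_predicted)
    eb = f(res_b.y_observed - res_b.y_predicted)
    diff = ea - eb
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(ea, eb)
    return ComparisonResult(
        method="paired_error_t",
        statistic=float(t),
        p_value=float(p),
        model_names=(res_a.model_name, res_b.model_name),
    )


def _rowwise_pearson(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Pearson r per row of two (B, N) matrices; NaN where undefined."""
    yc = y - y.mean(axis=1, keepdims=True)
    hc = yhat - yhat.mean(axis=1, keepdims=True)
    num = np.sum(yc * hc, axis=1)
    den = np.sqrt(np.sum(yc**2, axis=1) * np.sum(hc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def compare_bootstrap(
    res_a: PredictionResult,
    res_b: PredictionResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> ComparisonResult:
    """Paired bootstrap comparison of two accuracies, outcomes may differ.

    Participants are resampled with replacement *jointly* for both models;
    each replicate yields one accuracy per model. The two-sided p-value is
    the probability that the paired accuracy difference crosses zero,
    2 * min(P(dr <= 0), P(dr >= 0)) with ties at zero split between sides,
    capped at 1.
    """
    if res_a.n != res_b.n:
        raise AlignmentError(f"models cover {res_a.n} vs {res_b.n} participants")
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; the p-value will be coarse")
    rng = np.random.default_rng(seed)
    n = res_a.n
    idx = rng.integers(0, n, size=(n_boot, n))
    r_a = _rowwise_pearson(res_a.y_observed[idx], res_a.y_predicted[idx])
    r_b = _rowwise_pearson(res_b.y_observed[idx], res_b.y_predicted[idx])
    ok = np.isfinite(r_a) & np.isfinite(r_b)
    if not np.any(ok):
        raise UndefinedStatisticError("all bootstrap replicates had undefined accuracy")
    delta = r_a[ok] - r_b[ok]
    p_le = (np.sum(delta < 0) + 0.5 * np.sum(delta == 0)) / len(delta)
    p = min(1.0, 2.0 * min(p_le, 1.0 - p_le))
    return ComparisonResult(
        method="bootstrap_overlap",
        statistic=float(res_a.accuracy_r - res_b.accuracy_r),
        p_value=float(p),
        model_names=(res_a.model_name, res_b.model_name),
        n_boot=int(n_boot),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Reliability


def _item_matrix(items) -> np.ndarray:
    if isinstance(items, RatingScaleData):
        return items.values
    return np.asarray(items, dtype=float)


def _check_items(vals: np.ndarray, min_k: int = 2) -> None:
    if vals.ndim != 2 or vals.shape[1] < min_k:
        raise InvalidInputError(f"need an N x k item matrix with k >= {min_k}")
    spreads = np.ptp(vals, axis=0)
    if np.any(spreads == 0):
        j = int(np.flatnonzero(spreads == 0)[0])
        raise UndefinedStatisticError(f"item {j + 1} is constant; correlation undefined")


def inter_item_mean(items) -> float:
    """Mean of the k(k-1)/2 pairwise Pearson correlations among items."""
    vals = _item_matrix(items)
    _check_items(vals)
    corr = np.corrcoef(vals, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def corrected_item_total_mean(items) -> float:
    """Mean correlation of each item with the total of the *other* items."""
    vals = _item_matrix(items)
    _check_items(vals, min_k=3)
    total = vals.sum(axis=1)
    rs = []
    for j in range(vals.shape[1]):
        rest = total - vals[:, j]
        if np.ptp(rest) == 0:
            raise UndefinedStatisticError(f"rest-total for item {j + 1} is constant")
        rs.append(np.corrcoef(vals[:, j], rest)[0, 1])
    return float(np.mean(rs))


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    vals = _item_matrix(items)
    if vals.ndim != 2 or vals.shape[1] < 2:
        raise InvalidInputError("need an N x k item matrix with k >= 2")
    k = vals.shape[1]
    total_var = vals.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("total score has zero variance; alpha undefined")
    item_var = vals.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass(frozen=True)
class ReliabilityReport:
    """Reliability summary of one rating scale.

    ``test_retest`` holds user-supplied coefficients from prior studies
    (they cannot be estimated from a single administration); ``ceilings``
    maps each reliability estimate to the accuracy ceiling it implies.
    """

    scale_name: str
    inter_item_mean_r: float
    corrected_item_total_mean_r: float
    alpha: float
    test_retest: tuple[float, ...] = ()
    ceilings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scale_name": self.scale_name,
            "inter_item_mean_r": self.inter_item_mean_r,
            "corrected_item_total_mean_r": self.corrected_item_total_mean_r,
            "alpha": self.alpha,
            "test_retest": list(self.test_retest),
            "ceilings": dict(self.ceilings),
        }


def reliability_report(
    scale: RatingScaleData,
    test_retest: tuple[float, ...] = (),
    convention: str = "paper",
) -> ReliabilityReport:
    """Compute the full reliability summary for one scale."""
    stats_ = {
        "inter_item_mean_r": inter_item_mean(scale),
        "corrected_item_total_mean_r": corrected_item_total_mean(scale),
        "alpha": cronbach_alpha(scale),
    }
    ceilings = {
        name: reliability_ceiling(value, convention=convention)
        for name, value in stats_.items()
        if 0 < value <= 1
    }
    return ReliabilityReport(
        scale_name=scale.scale_name,
        test_retest=tuple(test_retest),
        ceilings=ceilings,
        **stats_,
    )


def reliability_ceiling(
    rel_predicted: float,
    rel_predictor: float | None = None,
    convention: str = "paper",
) -> float:
    """Upper bound on the accuracy of predicting an unreliable measure.

    ``paper`` convention: the observed accuracy is judged directly against
    the reliability value itself. ``classical`` convention: the attenuation
    bound sqrt(rel_predicted * rel_predictor) (predictor reliability taken
    as 1 when not supplied).
    """
    if not 0.0 < rel_predicted <= 1.0:
        raise InvalidParameterError("rel_predicted must be in (0, 1]")
    if convention == "paper":
        return float(rel_predicted)
    if convention == "classical":
        rp = 1.0 if rel_predictor is None else rel_predictor
        if not 0.0 < rp <= 1.0:
            raise InvalidParameterError("rel_predictor must be in (0, 1]")
        return float(np.sqrt(rel_predicted * rp))
    raise InvalidParameterError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Information content


@dataclass(frozen=True)
class DiversityReport:
    """Shannon entropy (bits) and diversity index 2^H of a token corpus."""

    entropy_bits: float
    diversity_index: float
    token_count: int
    distinct_tokens: int

    def to_dict(self) -> dict:
        return {
            "entropy_bits": self.entropy_bits,
            "diversity_index": self.diversity_index,
            "token_count": self.token_count,
            "distinct_tokens": self.distinct_tokens,
        }


def diversity_index(token_lists, normalize: bool = True) -> DiversityReport:
    """Diversity index 2^H of the pooled token frequency distribution.

    H is the Shannon entropy in bits of token relative frequencies across
    the whole corpus; 2^H is the effective number of distinct token types.
    Tokens are normalized (lowercased, punctuation stripped) by default with
    the same rule used for decontextualized embedding, so the index
    describes exactly the words the models saw.
    """
    from .embeddings import normalize_token

    tokens: list[str] = []
    for lst in token_lists:
        for tok in lst:
            if normalize:
                tok = normalize_token(tok)
            if tok:
                tokens.append(tok)
    if not tokens:
        raise InvalidInputError("empty corpus: no tokens to measure")
    counts = np.asarray(list(Counter(tokens).values()), dtype=float)
    h = float(stats.entropy(counts, base=2))
    return DiversityReport(
        entropy_bits=h,
        diversity_index=float(2.0**h),
        token_count=int(counts.sum()),
        distinct_tokens=len(counts),
    )


def word_count_stats(token_lists) -> tuple[float, float]:
    """Mean and SD (ddof=1) of per-response token counts."""
    counts = np.asarray([len(lst) for lst in token_lists], dtype=float)
    if len(counts) == 0:
        raise InvalidInputError("no responses")
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return float(counts.mean()), sd


# ---------------------------------------------------------------------------
# Interpretation


_R_BANDS = [
    (0.80, "very strong"),
    (0.60, "strong"),
    (0.40, "moderate"),
    (0.20, "weak"),
]


def interpret_r(r: float) -> str:
    """Interpretation band for a correlation magnitude.

    0.20-0.39 weak, 0.40-0.59 moderate, 0.60-0.79 strong, 0.80-1.0 very
    strong; below 0.20 is labelled "negligible".
    """
    if not np.isfinite(r) or abs(r) > 1.0:
        raise InvalidParameterError(f"correlation {r} outside [-1, 1]")
    mag = abs(r)
    for cut, label in _R_BANDS:
        if mag >= cut:
            return label
    return "negligible"
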