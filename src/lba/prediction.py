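"""Nested cross-validated ridge regression from embedding features to scale scores.

The training scheme: 10-fold outer cross-validation stratified on 4
quantile bins of the outcome; within each outer training set a single
stratified 75/25 analysis/assessment split chooses the ridge penalty from
a grid of 10^-16..10^16 (x10 steps); the model is then refit on the whole
outer training set at the selected penalty and predicts the held-out fold.
Accuracy is the Pearson correlation between the observed outcome and the
pooled out-of-fold predictions.

The ridge solve uses the SVD of the (standardized, centred) design, which
lets the entire penalty grid be evaluated from a single decomposition per
inner split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import PredictionResult, TrainingConfig
from .errors import InvalidInputError, InvalidParameterError, UndefinedStatisticError
from .utils import derive_seed, substream

__all__ = [
    "stratify_bins",
    "make_folds",
    "RidgeModel",
    "ridge_fit",
    "select_penalty",
    "cross_validated_predict",
    "difference_target",
]


# ---------------------------------------------------------------------------
# Stratification and fold assignment


def stratify_bins(y, n_bins: int) -> np.ndarray:
    """Quantile-bin a continuous outcome for stratified splitting.

    Observations are ranked (stable order for ties) and cut into ``n_bins``
    contiguous rank blocks, so bin sizes differ by at most one plus the
    number of tied boundary values. A constant outcome degenerates to a
    single bin with a warning.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise InvalidInputError("y must be a 1-D vector")
    n = len(y)
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    if n < n_bins:
        raise InvalidInputError(f"need at least n_bins={n_bins} observations, got {n}")
    if np.ptp(y) == 0:
        warnings.warn("constant outcome: stratification degenerates to a single bin")
        return np.zeros(n, dtype=int)
    order = np.argsort(y, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def make_folds(y, n_folds: int, n_bins: int, seed: int) -> np.ndarray:
    """Assign observations to cross-validation folds, stratified on ``y``.

    Members of each quantile bin are dealt to folds so that per-bin fold
    counts differ by at most one *and* the fold totals of the outcome are
    as equal as possible (rank-ordered dealing against cumulative fold
    sums, followed by within-bin swap refinement). Balancing the outcome
    totals matters because the accuracy of pooled out-of-fold predictions
    inherits a negative artifact equal to the between-fold share of
    outcome variance: a fold-constant predictor (the infinite-penalty
    limit) correlates at exactly minus that share, however small the
    fold-mean differences are. Deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds > n:
        raise InvalidParameterError(f"n_folds={n_folds} exceeds N={n}")
    if n_folds < 2:
        raise InvalidParameterError("n_folds must be >= 2")
    rng = substream(seed, "folds")
    bins = stratify_bins(y, n_bins)
    assignment = np.empty(n, dtype=int)
    fold_sizes = np.zeros(n_folds, dtype=int)
    fold_sums = np.zeros(n_folds)
    dev = y - y.mean()
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(len(members))]  # random order among ties
        members = members[np.argsort(y[members], kind="stable")]
        for start in range(0, len(members), n_folds):
            chunk = members[start : start + n_folds]
            # eligible folds: the currently smallest; the largest running
            # total receives the smallest outcome value in the chunk
            elig = np.argsort(fold_sizes, kind="stable")[: len(chunk)]
            elig = elig[np.argsort(-fold_sums[elig], kind="stable")]
            assignment[chunk] = elig
            fold_sizes[elig] += 1
            fold_sums[elig] += dev[chunk]
    _balance_fold_sums(y, bins, assignment, fold_sums)
    return assignment


def _balance_fold_sums(
    y: np.ndarray,
    bins: np.ndarray,
    assignment: np.ndarray,
    fold_sums: np.ndarray,
    max_iter: int = 200,
) -> None:
    """Within-bin swaps between the extreme folds until totals nearly agree.

    Swapping two members of the same stratification bin preserves per-bin
    fold counts; each swap moves the largest and smallest fold totals
    toward each other. Stops once the spread is below half the smallest
    within-bin outcome gap (for integer totals: a gap of at most ~1).
    """
    if np.ptp(fold_sums) == 0:
        return
    for _ in range(max_iter):
        hi = int(np.argmax(fold_sums))
        lo = int(np.argmin(fold_sums))
        gap = fold_sums[hi] - fold_sums[lo]
        if gap <= 1e-9:
            return
        best = None
        for b in np.unique(bins):
            in_hi = np.flatnonzero((assignment == hi) & (bins == b))
            in_lo = np.flatnonzero((assignment == lo) & (bins == b))
            if len(in_hi) == 0 or len(in_lo) == 0:
                continue
            diff = y[in_hi][:, None] - y[in_lo][None, :]
            j = np.unravel_index(np.argmin(np.abs(diff - gap / 2.0)), diff.shape)
            d = float(diff[j])
            if 0.0 < d < gap and (best is None or abs(d - gap / 2.0) < best[0]):
                best = (abs(d - gap / 2.0), int(in_hi[j[0]]), int(in_lo[j[1]]), d)
        if best is None:
            return
        _, a, b_, d = best
        assignment[a], assignment[b_] = lo, hi
        fold_sums[hi] -= d
        fold_sums[lo] += d


def _stratified_holdout(y, frac_holdout: float, n_bins: int, rng: np.random.Generator):
    """Indices of a stratified holdout of roughly ``frac_holdout`` of rows."""
    n = len(y)
    bins = stratify_bins(np.asarray(y, dtype=float), min(n_bins, max(1, n // 2)))
    holdout: list[np.ndarray] = []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(len(members))]
        k = int(round(len(members) * frac_holdout))
        holdout.append(members[:k])
    hold = np.sort(np.concatenate(holdout))
    if len(hold) == 0 or len(hold) == n:  # tiny-sample guard
        hold = np.array([int(rng.integers(n))])
    mask = np.zeros(n, dtype=bool)
    mask[hold] = True
    return np.flatnonzero(~mask), hold


# ---------------------------------------------------------------------------
# Ridge


@dataclass(frozen=True)
class RidgeModel:
    """A fitted ridge regression with unpenalized intercept.

    Coefficients are expressed per (optionally standardized) feature;
    ``feature_center``/``feature_scale`` store the training-fold transform
    that is re-applied to new data at prediction time.
    """

    coefficients: np.ndarray
    intercept: float
    penalty: float
    feature_center: np.ndarray
    feature_scale: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.feature_center) / self.feature_scale
        return self.intercept + Z @ self.coefficients


def _fit_transform(X: np.ndarray, standardize: bool):
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(X.shape[1])
    return (X - center) / scale, center, scale


def _ridge_path(Z: np.ndarray, yc: np.ndarray, penalties: np.ndarray) -> np.ndarray:
    """Coefficients for every penalty from one SVD of the centred design.

    Returns an array of shape (len(penalties), n_features).
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uty = U.T @ yc
    denom = s[None, :] ** 2 + penalties[:, None]
    factor = np.divide(s[None, :], denom, out=np.zeros_like(denom), where=denom > 0)
    return (factor * uty[None, :]) @ Vt


def ridge_fit(X, y, penalty: float, standardize: bool = True) -> RidgeModel:
    """Fit ridge regression minimising ||y - Xb - a||^2 + penalty * ||b||^2.

    The intercept is unpenalized (features and outcome are centred before
    the penalized solve); with ``standardize`` the features are also scaled
    to unit variance within the training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise InvalidInputError(f"incompatible shapes X{X.shape}, y{y.shape}")
    if X.shape[0] < 2:
        raise InvalidInputError("need at least 2 rows to fit")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite values in training data")
    if penalty < 0:
        raise InvalidParameterError("penalty must be >= 0")
    Z, center, scale = _fit_transform(X, standardize)
    yc = y - y.mean()
    beta = _ridge_path(Z, yc, np.asarray([float(penalty)]))[0]
    return RidgeModel(
        coefficients=beta,
        intercept=float(y.mean()),
        penalty=float(penalty),
        feature_center=center,
        feature_scale=scale,
    )


def select_penalty(
    X,
    y,
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Choose the ridge penalty on a stratified analysis/assessment split.

    75% of the rows (stratified on quantile bins of ``y``) fit one model per
    grid penalty; the remaining 25% score them by squared prediction error.
    Under the default ``min_rmse_1se`` rule the chosen penalty is the
    *largest* one whose assessment mean squared error is within one
    standard error of the minimum — the usual guard against the winner's
    curse of comparing 33 penalties on one noisy holdout, without which
    spurious low-penalty fits are selected often enough to skew the null
    distribution of the downstream accuracy. ``min_rmse`` gives the plain
    minimiser (ties to the smallest penalty).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = substream(config.seed, "penalty-selection")
    ana, ass = _stratified_holdout(
        y, 1.0 - config.inner_analysis_fraction, config.n_strat_bins, rng
    )
    grid = config.grid()
    Z, center, scale = _fit_transform(X[ana], config.standardize_features)
    y_ana = y[ana]
    betas = _ridge_path(Z, y_ana - y_ana.mean(), grid)
    Z_ass = (X[ass] - center) / scale
    preds = y_ana.mean() + Z_ass @ betas.T  # (n_assess, n_penalties)
    sq_err = (preds - y[ass, None]) ** 2
    mse = sq_err.mean(axis=0)
    best = int(np.argmin(mse))
    if config.selection_rule == "min_rmse" or len(ass) < 2:
        return float(grid[best])
    se_best = float(sq_err[:, best].std(ddof=1) / np.sqrt(len(ass)))
    within = np.flatnonzero(mse <= mse[best] + se_best)
    return float(grid[int(within.max())])


def cross_validated_predict(
    X,
    y,
    config: TrainingConfig | None = None,
    outcome_name: str = "outcome",
    model_name: str = "",
) -> PredictionResult:
    """Out-of-fold ridge predictions under the nested scheme.

    For each outer fold the penalty is selected on the training part alone,
    the model refit on the full training part at that penalty, and the
    held-out fold predicted. Accuracy is computed once on the pooled
    out-of-fold vector.
    """
    from .evaluation import pearson_r  # local import avoids a cycle at module load

    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise InvalidInputError(f"X has {X.shape[0]} rows but y has {len(y)}")
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("outcome is constant; accuracy would be undefined")
    n = len(y)
    folds = make_folds(y, config.n_folds, config.n_strat_bins, seed=config.seed)
    yhat = np.full(n, np.nan)
    penalties = []
    for k in range(config.n_folds):
        test = np.flatnonzero(folds == k)
        train = np.flatnonzero(folds != k)
        rng = substream(config.seed, f"inner-split-fold-{k}")
        lam = select_penalty(X[train], y[train], config, rng=rng)
        model = ridge_fit(X[train], y[train], lam, config.standardize_features)
        yhat[test] = model.predict(X[test])
        penalties.append(lam)
    assert not np.any(np.isnan(yhat)), "incomplete out-of-fold prediction"
    if np.ptp(yhat) == 0:
        raise UndefinedStatisticError("out-of-fold predictions are constant; accuracy undefined")
    r, p = pearson_r(y, yhat)
    return PredictionResult(
        y_observed=y,
        y_predicted=yhat,
        fold_assignment=folds,
        fold_penalties=tuple(penalties),
        accuracy_r=r,
        accuracy_p=p,
        outcome_name=outcome_name,
        model_name=model_name,
    )


def difference_target(y1, y2) -> np.ndarray:
    """Discriminant difference score: column-mean-centred y1 minus centred y2.

    Used to train models that distinguish two strongly correlated scales;
    the result always has mean zero.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if len(y1) != len(y2):
        raise InvalidInputError(f"length mismatch: {len(y1)} vs {len(y2)}")
    return (y1 - y1.mean()) - (y2 - y2.mean())
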