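"""Pairwise co-abundance estimation.

Two estimators are provided, mirroring the two standard data regimes:

* :class:`BootstrapSpearman` — bootstrapped Spearman rank correlation for
  genome-level shotgun abundance tables.  The point estimate is the median
  over resamples; edges whose percentile confidence interval spans zero can
  be zeroed ("non-robust" edges), keeping the matrix complete for the
  downstream 1−r distance conversion.
* :class:`SparCC` — the log-ratio-variance estimator of "basis"
  correlations for compositional count data (16S OTU/ASV tables), with the
  iterative exclusion of strongly correlated pairs under the
  sparse-correlation approximation.

Both follow the scikit-learn estimator protocol: ``fit(X)`` with
``X`` of shape (n_samples, n_features), fitted attribute ``correlation_``.
Module-level functions wrap them for :class:`~guildflow.containers.FeatureTable`
inputs and return :class:`CorrelationMatrix` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import FeatureTable

logger = logging.getLogger("guildflow")

__all__ = [
    "CorrelationMatrix",
    "SpearmanCorrelation",
    "BootstrapSpearman",
    "SparCC",
    "spearman_matrix",
    "bootstrap_spearman",
    "sparcc",
]


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise co-abundance coefficients with provenance."""

    feature_ids: list[str]
    r: np.ndarray
    method: str
    support: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.feature_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match feature ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("correlation coefficients must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be 1")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=float)
            if self.support.shape != (n, n):
                raise ValueError("support shape mismatch")


def _check_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples-by-features array")
    return X


def _constant_columns(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        mins = np.nanmin(X, axis=0)
        maxs = np.nanmax(X, axis=0)
    return ~(maxs > mins)


# ----------------------------------------------------------------------
# plain Spearman
# ----------------------------------------------------------------------
class SpearmanCorrelation(BaseEstimator):
    """Spearman rank correlation, pairwise-complete over missing values.

    Ties receive average ranks.  Pairs with fewer than 3 overlapping
    observations get the neutral value 0 (logged loudly) so the matrix stays
    complete.  Constant features are an error: the caller must remove them.
    """

    def __init__(self, min_periods: int = 3):
        self.min_periods = min_periods

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n_samples, n_features = X.shape
        if n_samples < 3:
            raise ValueError("need at least 3 samples for Spearman correlation")
        const = _constant_columns(X)
        if const.any():
            raise ValueError(
                f"constant feature(s) at column(s) {np.flatnonzero(const).tolist()}; "
                "remove before correlation"
            )
        df = pd.DataFrame(X)
        r = df.corr(method="spearman", min_periods=self.min_periods).to_numpy()
        missing = np.isnan(r)
        if missing.any():
            logger.warning(
                "%d feature pair(s) had < %d overlapping samples; "
                "their correlation is set to 0",
                int(missing.sum() // 2), self.min_periods,
            )
            r[missing] = 0.0
        np.fill_diagonal(r, 1.0)
        self.correlation_ = np.clip(r, -1.0, 1.0)
        self.n_features_in_ = n_features
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).correlation_


# ----------------------------------------------------------------------
# bootstrapped Spearman
# ----------------------------------------------------------------------
class BootstrapSpearman(BaseEstimator):
    """Bootstrapped Spearman correlation with a robustness filter.

    For each of ``n_boot`` resamples (samples drawn with replacement) the
    full Spearman matrix is computed; the point estimate is the elementwise
    median.  ``support_`` holds the fraction of resamples agreeing in sign
    with the median.  With ``filter_nonrobust`` the entries whose percentile
    CI at ``ci_level`` spans zero are set to 0.

    Co-abundance network inference is unreliable below ~25 samples; a
    warning is emitted in that regime.
    """

    def __init__(
        self,
        n_boot: int = 1000,
        ci_level: float = 0.95,
        filter_nonrobust: bool = True,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.filter_nonrobust = filter_nonrobust
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n_samples, n_features = X.shape
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if n_samples < 3:
            raise ValueError("need at least 3 samples")
        if n_samples < 25:
            logger.warning(
                "only %d samples: a minimum of 25 is recommended for robust "
                "co-abundance estimation", n_samples,
            )
        if np.isnan(X).any():
            raise ValueError("bootstrap path requires a complete table (no NaN)")
        const = _constant_columns(X)
        if const.any():
            raise ValueError(
                f"constant feature(s) at column(s) {np.flatnonzero(const).tolist()}"
            )
        rng = np.random.default_rng(self.random_state)
        boots = np.empty((self.n_boot, n_features, n_features), dtype=np.float32)
        for b in range(self.n_boot):
            idx = rng.integers(0, n_samples, size=n_samples)
            Xi = X[idx]
            ranks = stats.rankdata(Xi, axis=0)
            sd = ranks.std(axis=0)
            degenerate = sd == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                rb = np.corrcoef(ranks, rowvar=False)
            if degenerate.any():
                rb[degenerate, :] = np.nan
                rb[:, degenerate] = np.nan
            boots[b] = rb
        valid = ~np.isnan(boots)
        n_valid = valid.sum(axis=0)
        if (n_valid == 0).any():
            raise ValueError("all bootstrap resamples degenerate for some pair")
        with np.errstate(invalid="ignore"):
            r = np.nanmedian(boots, axis=0)
            alpha = 1.0 - self.ci_level
            lo = np.nanpercentile(boots, 100 * alpha / 2.0, axis=0)
            hi = np.nanpercentile(boots, 100 * (1 - alpha / 2.0), axis=0)
            sign_match = np.sign(boots) == np.sign(r)[None, :, :]
            support = np.where(
                n_valid > 0, (sign_match & valid).sum(axis=0) / np.maximum(n_valid, 1), 0.0
            )
        support[np.sign(r) == 0] = 1.0  # a zero median is "supported" by definition
        if self.filter_nonrobust:
            spans_zero = (lo <= 0.0) & (hi >= 0.0)
            r = np.where(spans_zero, 0.0, r)
            self.ci_low_, self.ci_high_ = lo, hi
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        support = (support + support.T) / 2.0
        np.fill_diagonal(support, 1.0)
        self.correlation_ = r.astype(float)
        self.support_ = support.astype(float)
        self.n_features_in_ = n_features
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).correlation_


# ----------------------------------------------------------------------
# SparCC
# ----------------------------------------------------------------------
class SparCC(BaseEstimator):
    """Basis correlations from compositional counts via log-ratio variances.

    For components i, j with observed fractions x_i, x_j, the variation
    t_ij = var(log(x_i / x_j)) decomposes as
    ``t_ij = w_i^2 + w_j^2 - 2 r_ij w_i w_j`` in terms of the (unobserved)
    basis log-variances w^2 and basis correlations r.  Under the sparsity
    assumption that most correlations are near zero, the basis variances
    solve the linear system ``[(D-2) I + J] w^2 = t  row-sums``.  Pairs whose
    estimated |r| exceeds ``exclusion_threshold`` are then iteratively
    excluded from the approximation and the system re-solved, up to
    ``n_exclusion_iter`` rounds.

    Zeros are handled with a pseudocount by default (deterministic point
    estimate); setting ``n_inner > 1`` averages over Dirichlet resamples of
    the composition instead, following the originally published procedure.
    """

    def __init__(
        self,
        n_exclusion_iter: int = 20,
        exclusion_threshold: float = 0.1,
        pseudocount: float = 1.0,
        n_inner: int = 1,
        random_state: int | None = None,
    ):
        self.n_exclusion_iter = n_exclusion_iter
        self.exclusion_threshold = exclusion_threshold
        self.pseudocount = pseudocount
        self.n_inner = n_inner
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n_samples, n_features = X.shape
        if n_features < 4:
            raise ValueError(
                "SparCC needs at least 4 features for the basis approximation"
            )
        if np.isnan(X).any():
            raise ValueError("SparCC requires a complete counts table")
        if (X < 0).any():
            raise ValueError("SparCC requires nonnegative counts")
        rng = np.random.default_rng(self.random_state)
        mats = []
        excl_counts = []
        for _ in range(max(1, self.n_inner)):
            if self.n_inner > 1:
                fractions = _dirichlet_fractions(X, self.pseudocount, rng)
            else:
                pseudo = X + self.pseudocount
                fractions = pseudo / pseudo.sum(axis=1, keepdims=True)
            r, n_excluded = _sparcc_once(
                np.log(fractions),
                self.n_exclusion_iter,
                self.exclusion_threshold,
            )
            mats.append(r)
            excl_counts.append(n_excluded)
        r = np.mean(mats, axis=0)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        self.correlation_ = r
        self.n_excluded_pairs_ = int(np.mean(excl_counts))
        self.n_features_in_ = n_features
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).correlation_


def _dirichlet_fractions(X: np.ndarray, pseudocount: float, rng) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    for s in range(X.shape[0]):
        out[s] = rng.dirichlet(X[s] + pseudocount)
    return out


def _sparcc_once(
    logx: np.ndarray, n_iter: int, threshold: float
) -> tuple[np.ndarray, int]:
    """One SparCC pass on log-fractions of shape (n_samples, D)."""
    n, D = logx.shape
    # variation matrix t_ij = var(log x_i - log x_j) = v_i + v_j - 2 c_ij
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    T = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(T, 0.0)

    include = np.ones((D, D), dtype=bool)  # pairs used in the approximation
    np.fill_diagonal(include, False)
    n_excluded = 0
    r = None
    for it in range(n_iter + 1):
        M = include.astype(float)
        np.fill_diagonal(M, 0.0)
        deg = M.sum(axis=1)
        A = M + np.diag(np.maximum(deg, 1.0))
        t_row = (T * include).sum(axis=1)
        try:
            w2 = np.linalg.solve(A, t_row)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate exclusion
            w2 = np.linalg.lstsq(A, t_row, rcond=None)[0]
        bad = w2 <= 0
        if bad.any():
            logger.warning(
                "SparCC: %d negative basis variance(s) clipped", int(bad.sum())
            )
            w2 = np.where(bad, 1e-12, w2)
        w = np.sqrt(w2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (w2[:, None] + w2[None, :] - T) / (2.0 * np.outer(w, w))
        np.fill_diagonal(r, 1.0)
        if it == n_iter:
            break
        # exclude the most strongly correlated still-included pair
        masked = np.where(include, np.abs(r), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        include[i, j] = include[j, i] = False
        n_excluded += 1
    return np.clip(r, -1.0, 1.0), n_excluded


# ----------------------------------------------------------------------
# FeatureTable-level wrappers
# ----------------------------------------------------------------------
def _named_matrix(est, ft: FeatureTable, method: str, params: dict) -> CorrelationMatrix:
    check_is_fitted(est)
    return CorrelationMatrix(
        feature_ids=ft.feature_ids,
        r=est.correlation_,
        method=method,
        support=getattr(est, "support_", None),
        params=params,
    )


def spearman_matrix(ft: FeatureTable) -> CorrelationMatrix:
    """Plain Spearman correlation between the features of ``ft``."""
    est = SpearmanCorrelation().fit(ft.values.T)
    return _named_matrix(est, ft, "spearman_plain", {})


def bootstrap_spearman(
    ft: FeatureTable,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    filter_nonrobust: bool = True,
    seed: int | None = None,
) -> CorrelationMatrix:
    """Bootstrapped Spearman correlation between the features of ``ft``."""
    est = BootstrapSpearman(
        n_boot=n_boot,
        ci_level=ci_level,
        filter_nonrobust=filter_nonrobust,
        random_state=seed,
    ).fit(ft.values.T)
    params = {
        "n_boot": n_boot,
        "ci_level": ci_level,
        "filter_nonrobust": filter_nonrobust,
        "seed": seed,
    }
    return _named_matrix(est, ft, "spearman_bootstrap", params)


def sparcc(
    ft: FeatureTable,
    n_exclusion_iter: int = 20,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
    n_inner: int = 1,
    seed: int | None = None,
) -> CorrelationMatrix:
    """SparCC basis correlations for a counts FeatureTable."""
    if ft.unit != "counts":
        raise ValueError("SparCC operates on counts tables")
    est = SparCC(
        n_exclusion_iter=n_exclusion_iter,
        exclusion_threshold=exclusion_threshold,
        pseudocount=pseudocount,
        n_inner=n_inner,
        random_state=seed,
    ).fit(ft.values.T)
    params = {
        "n_exclusion_iter": n_exclusion_iter,
        "exclusion_threshold": exclusion_threshold,
        "pseudocount": pseudocount,
        "n_inner": n_inner,
        "seed": seed,
        "n_excluded_pairs": est.n_excluded_pairs_,
    }
    return _named_matrix(est, ft, "sparcc", params)
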