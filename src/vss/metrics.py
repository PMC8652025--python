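"""Evaluation metrics: quality-of-fit log likelihood and variance instability.

Two complementary checks of whether a mean–variance model (or the transform
derived from it) matches a replicated dataset:

*   **Gaussian quality-of-fit** — the average log density of the auxiliary
    signal under a Gaussian centred at the base signal with sd given by the
    candidate curve, ``mean_i log N(x_aux_i | x_base_i, sigma(x_base_i))``.
    A Gaussian is used because it is the maximum-entropy distribution for a
    given mean and variance; the score is maximized when the candidate
    matches the conditional variance of the data.

*   **Variance instability** — sort positions by transformed base value,
    chunk into bins of ``b`` (default 10 000), and let ``v_j`` be the sum of
    squared between-replicate differences in bin *j*.  The score is
    ``var(v_1..B) / (sigma_1**2 * sigma_2**2)``, where ``sigma_1`` and
    ``sigma_2`` are the sds of the two transformed vectors.  The
    normalization makes the score invariant under rescaling ``t -> alpha*t``;
    a perfectly stabilized signal scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .mv_curve import BaseAuxPairs, BinStats, compute_bin_stats


@dataclass
class FitReport:
    """Average Gaussian log density of aux given base (nats/position)."""

    mean_log_density: float
    n_positions: int
    sigma_source: str = ""


@dataclass
class InstabilityReport:
    """Variance-instability score with its ingredients."""

    score: float
    v: np.ndarray          # per-bin (sum or mean) squared differences
    n_bins: int
    sigma1: float
    sigma2: float
    bin_size: int
    per_position: bool = False


def gaussian_fit_loglik(pairs: BaseAuxPairs, sigma_fn, sigma_source: str = "") -> FitReport:
    """Average log density of ``aux_i ~ N(base_i, sigma_fn(base_i))``.

    ``sigma_fn`` maps base values to positive standard deviations (a fitted
    :class:`~vss.mv_curve.MeanVarianceCurve`, a transform's
    ``implied_sigma``, or any callable).
    """
    if len(pairs) == 0:
        raise ValidationError("cannot evaluate likelihood of empty pairs")
    sigma = np.asarray(sigma_fn(pairs.base), dtype=np.float64)
    if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
        raise ValidationError("sigma must be positive and finite for every base value")
    ll = norm.logpdf(pairs.aux, loc=pairs.base, scale=sigma)
    return FitReport(float(ll.mean()), len(pairs), sigma_source)


def variance_instability(
    base_t,
    aux_t,
    b: int = 10_000,
    per_position: bool = False,
) -> InstabilityReport:
    """Variance-instability score of a pair of transformed signal vectors.

    Positions are sorted by ``base_t`` (stable, original index as tiebreak)
    and chunked into ``B = floor(n/b)`` full bins; the trailing remainder is
    discarded (a partial bin's sum is not comparable to full bins').  With
    ``per_position=True``, ``v_j`` is the mean rather than the sum of squared
    differences.  Variances are population (1/n) throughout; ``sigma1`` /
    ``sigma2`` are computed over the full input vectors.
    """
    base_t = np.asarray(base_t, dtype=np.float64)
    aux_t = np.asarray(aux_t, dtype=np.float64)
    if base_t.shape != aux_t.shape or base_t.ndim != 1:
        raise ValidationError("base_t and aux_t must be 1-D vectors of equal length")
    n = len(base_t)
    if n < 2 * b:
        raise ValidationError(
            f"variance instability needs at least 2 full bins: n={n} < 2*b={2 * b}"
        )
    order = np.argsort(base_t, kind="stable")
    d2 = (base_t[order] - aux_t[order]) ** 2
    n_bins = n // b
    v = d2[: n_bins * b].reshape(n_bins, b).sum(axis=1)
    if per_position:
        v = v / b
    sigma1 = float(base_t.std())
    sigma2 = float(aux_t.std())
    denom = sigma1 ** 2 * sigma2 ** 2
    if denom == 0:
        raise ValidationError("constant transformed signal: variance normalization is zero")
    return InstabilityReport(
        score=float(v.var() / denom),
        v=v,
        n_bins=int(n_bins),
        sigma1=sigma1,
        sigma2=sigma2,
        bin_size=int(b),
        per_position=per_position,
    )


def mean_variance_diagnostic(pairs: BaseAuxPairs, b: int, zero_bin: bool = False):
    """Binned (mean, sd) scatter of a base/aux pairing, for inspection of
    the mean–variance relationship before or after transformation.

    Returns the :meth:`~vss.mv_curve.BinStats.to_dataframe` table with
    columns ``mu``, ``sigma``, ``count`` and ``is_zero_bin``.
    """
    stats: BinStats = compute_bin_stats(pairs, b, zero_bin=zero_bin)
    return stats.to_dataframe()[["mu", "sigma", "count", "is_zero_bin"]]
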