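"""Estimating the empirical mean–variance relationship from replicates.

Sequencing-based signals are heteroscedastic: the between-replicate variance
of the signal at a position depends on its mean level.  Writing ``mu_i`` for
the latent mean at position *i* and assuming ``var(x_i) = sigma(mu_i)**2``,
this module estimates the curve ``sigma(mu)`` empirically:

1.  All ordered pairs of replicates are concatenated into two aligned
    vectors ``x_base`` and ``x_aux`` of length ``N*M*(M-1)``
    (:func:`build_base_aux`).
2.  Positions are sorted by ``x_base`` and chunked into bins of ``b``
    entries; per bin the mean and (population) standard deviation of
    ``x_aux`` give a point estimate ``(mu_j, sigma_j)``
    (:func:`compute_bin_stats`).  Zero-inflated signal types get a
    dedicated bin for positions with ``x_base == 0``.
3.  Bin variances are smoothed across neighbouring bins with exponentially
    decaying weights ``2**(-b*|k|/beta)`` over a window of ``2w+1`` bins,
    ``w = round(-beta*log(0.01) / (b*log(2)))`` (:func:`smooth_bin_sigmas`).
4.  A cubic smoothing spline of ``sigma_j`` against ``mu_j`` — smoothing
    parameter chosen by generalized cross-validation — yields the continuous
    curve ``sigma_hat(mu)``, clamped away from zero (:func:`fit_sigma_curve`).

``b`` and ``beta`` trade bias against variance: large values average over
many positions (low variance), small values keep bins homogeneous (low
bias).  Defaults per signal type are ``(b=1e5, beta=1e3)`` with a zero bin
for raw/FE signals and ``(b=1e3, beta=1e7)`` without one for LPPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .errors import ValidationError
from .signal_io import ReplicateSet

#: (b, beta, use zero bin) defaults per signal type
DEFAULT_HYPERPARAMETERS = {
    "raw": (100_000, 1e3, True),
    "fe": (100_000, 1e3, True),
    "lppv": (1_000, 1e7, False),
}

#: minimum number of distinct mean points the spline fit needs
MIN_SPLINE_POINTS = 4


def default_hyperparameters(signal_type: str):
    """Return ``(b, beta, zero_bin)`` defaults for a signal type."""
    try:
        return DEFAULT_HYPERPARAMETERS[signal_type]
    except KeyError:
        raise ValidationError(f"unknown signal type {signal_type!r}") from None


# ---------------------------------------------------------------------------
# Base / auxiliary pair construction
# ---------------------------------------------------------------------------

@dataclass
class BaseAuxPairs:
    """All ordered replicate pairs as two aligned value vectors.

    For M replicates over N aligned positions both vectors have length
    ``N*M*(M-1)``; entry *i* records the signal of one replicate (base) and
    of a different replicate (aux) at the same genomic position.
    """

    base: np.ndarray
    aux: np.ndarray

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=np.float64)
        self.aux = np.asarray(self.aux, dtype=np.float64)
        if self.base.shape != self.aux.shape or self.base.ndim != 1:
            raise ValidationError("base and aux must be 1-D vectors of equal length")

    def __len__(self) -> int:
        return len(self.base)


def build_base_aux(reps: ReplicateSet) -> BaseAuxPairs:
    """Enumerate every ordered pair of replicates into base/aux vectors.

    Pairs (i, j), i != j, are taken in lexicographic order of (i, j); within
    each pair, positions keep their genomic order.  For replicate pair
    (i, j), replicate i contributes to ``base`` and replicate j to ``aux``.
    """
    values = reps.values  # (M, N); ReplicateSet guarantees alignment
    m = reps.m_replicates
    base_parts, aux_parts = [], []
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            base_parts.append(values[i])
            aux_parts.append(values[j])
    return BaseAuxPairs(np.concatenate(base_parts), np.concatenate(aux_parts))


# ---------------------------------------------------------------------------
# Binned statistics
# ---------------------------------------------------------------------------

@dataclass
class BinStats:
    """Per-bin mean/sd estimates of the auxiliary signal.

    Arrays cover the non-zero bins in increasing order of base value; a
    final partial bin (fewer than ``b`` members) is kept and its actual
    count recorded.  The zero bin, when present, is stored separately: it
    never participates in cross-bin smoothing.
    """

    mu: np.ndarray               # mean of aux per bin
    sigma: np.ndarray            # population sd of aux per bin
    count: np.ndarray            # members per bin
    b: int                       # nominal bin size
    smoothed_sigma: Optional[np.ndarray] = None
    zero_mu: Optional[float] = None
    zero_sigma: Optional[float] = None
    zero_count: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.mu)

    @property
    def has_zero_bin(self) -> bool:
        return self.zero_mu is not None

    def to_dataframe(self):
        """Tabular view (one row per bin, zero bin first when present)."""
        import pandas as pd

        sm = self.smoothed_sigma if self.smoothed_sigma is not None else np.full(self.n_bins, np.nan)
        rows = {
            "mu": self.mu,
            "sigma": self.sigma,
            "smoothed_sigma": sm,
            "count": self.count,
            "is_zero_bin": np.zeros(self.n_bins, dtype=bool),
        }
        df = pd.DataFrame(rows)
        if self.has_zero_bin:
            zero = pd.DataFrame(
                {
                    "mu": [self.zero_mu],
                    "sigma": [self.zero_sigma],
                    "smoothed_sigma": [np.nan],
                    "count": [self.zero_count],
                    "is_zero_bin": [True],
                }
            )
            df = pd.concat([zero, df], ignore_index=True)
        return df


def compute_bin_stats(pairs: BaseAuxPairs, b: int, zero_bin: bool = True) -> BinStats:
    """Sort pairs by base value, chunk into bins of ``b``, and estimate
    per-bin mean and sd of the auxiliary values.

    The sort is stable with the original index as tiebreak.  Variances use
    the population (1/count) convention.  With ``zero_bin=True``, positions
    with base exactly 0 are set aside first and summarized separately.
    """
    if b < 2:
        raise ValidationError("bin size b must be at least 2")
    if len(pairs) == 0:
        raise ValidationError("cannot bin an empty base/aux pairing")

    base, aux = pairs.base, pairs.aux
    zero_mu = zero_sigma = None
    zero_count = 0
    if zero_bin:
        zmask = base == 0.0
        zero_count = int(zmask.sum())
        if zero_count:
            zero_mu = float(aux[zmask].mean())
            zero_sigma = float(aux[zmask].std())  # population sd
        base, aux = base[~zmask], aux[~zmask]

    if len(base) == 0:
        raise ValidationError("no non-zero positions to bin")
    if len(base) < b:
        warnings.warn(
            f"only {len(base)} non-zero positions for bin size b={b}; using a single bin",
            stacklevel=2,
        )

    order = np.argsort(base, kind="stable")
    aux_sorted = aux[order]
    n = len(aux_sorted)
    n_bins = int(np.ceil(n / b))
    mu = np.empty(n_bins)
    sigma = np.empty(n_bins)
    count = np.empty(n_bins, dtype=np.int64)
    for j in range(n_bins):
        chunk = aux_sorted[j * b : (j + 1) * b]
        mu[j] = chunk.mean()
        sigma[j] = chunk.std()
        count[j] = len(chunk)
    return BinStats(
        mu=mu, sigma=sigma, count=count, b=b,
        zero_mu=zero_mu, zero_sigma=zero_sigma, zero_count=zero_count,
    )


def smooth_bin_sigmas(stats: BinStats, beta: float, b: Optional[int] = None) -> BinStats:
    """Smooth bin variances across neighbouring bins.

    Bin ``j + k`` enters bin *j*'s estimate with weight ``2**(-b*|k|/beta)``
    over the window ``k = -w..w``, ``w = round(-beta*log(0.01)/(b*log(2)))``
    (the window containing all bins of weight >= 0.01), floored at 0.
    Neighbours beyond the first/last bin are dropped and the weights
    renormalized.  Smoothing averages *variances*; the stored
    ``smoothed_sigma`` is the square root.  The zero bin is untouched.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    b = stats.b if b is None else b
    sigma2 = stats.sigma ** 2
    n_bins = len(sigma2)
    w = max(0, round(-beta * np.log(0.01) / (b * np.log(2))))
    if w == 0 or n_bins == 1:
        smoothed = stats.sigma.copy()
    else:
        offsets = np.arange(-w, w + 1)
        weights = 2.0 ** (-b * np.abs(offsets) / beta)
        # 'same'-mode correlation plus renormalization == edge truncation
        kernel = weights[::-1]
        num = np.convolve(sigma2, kernel, mode="same")
        den = np.convolve(np.ones(n_bins), kernel, mode="same")
        if len(kernel) > n_bins:
            # numpy's 'same' window centering differs once the kernel is the
            # longer array; fall back to an explicit (small) computation
            num = np.array([
                (weights[max(0, j - w) - j + w : min(n_bins, j + w + 1) - j + w]
                 * sigma2[max(0, j - w) : min(n_bins, j + w + 1)]).sum()
                for j in range(n_bins)
            ])
            den = np.array([
                weights[max(0, j - w) - j + w : min(n_bins, j + w + 1) - j + w].sum()
                for j in range(n_bins)
            ])
        smoothed = np.sqrt(num / den)
    return replace(stats, smoothed_sigma=smoothed)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

@dataclass
class MeanVarianceCurve:
    """Continuous, strictly positive estimate ``sigma_hat(mu)``.

    Evaluation clamps below at ``sigma_floor`` and extrapolates constantly
    outside ``[mu_min, mu_max]``.  ``metadata`` records how the curve was
    fitted (b, beta, smoothing parameter, signal type, training
    chromosomes).
    """

    _fn: Callable[[np.ndarray], np.ndarray]
    mu_min: float
    mu_max: float
    sigma_floor: float
    metadata: dict = field(default_factory=dict)

    def __call__(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        clipped = np.clip(u, self.mu_min, self.mu_max)
        return np.maximum(np.asarray(self._fn(clipped), dtype=np.float64), self.sigma_floor)

    def clamp_activations(self, n_grid: int = 512) -> int:
        """Number of evaluation-grid points where the floor clamp binds."""
        grid = np.linspace(self.mu_min, self.mu_max, n_grid)
        raw = np.asarray(self._fn(grid), dtype=np.float64)
        return int(np.sum(raw < self.sigma_floor))

    @classmethod
    def from_function(cls, fn, domain, sigma_floor: float = 1e-4, metadata=None) -> "MeanVarianceCurve":
        """Wrap an analytic ``sigma(mu)`` (used for testing and for known
        mean-variance laws)."""
        lo, hi = float(domain[0]), float(domain[1])
        return cls(fn, lo, hi, sigma_floor, dict(metadata or {}))

    @classmethod
    def from_grid(cls, mu, sigma, sigma_floor: float, metadata=None) -> "MeanVarianceCurve":
        """Piecewise-linear curve through ``(mu, sigma)`` points (used when
        loading a serialized model; exact at the grid points)."""
        mu = np.asarray(mu, dtype=np.float64)
        sigma = np.asarray(sigma, dtype=np.float64)
        return cls(
            lambda u: np.interp(u, mu, sigma),
            float(mu[0]), float(mu[-1]), float(sigma_floor), dict(metadata or {}),
        )


def fit_sigma_curve(
    stats: BinStats,
    cv: bool = True,
    p_override: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> MeanVarianceCurve:
    """Fit a cubic smoothing spline of smoothed bin sd against bin mean.

    The spline minimizes a penalized least-squares objective (squared error
    weighted by bin occupancy plus a roughness penalty on the second
    derivative); the penalty weight is chosen by generalized
    cross-validation unless ``p_override`` pins it.  The zero-bin point
    ``(mu_0, sigma_0)`` joins the fit as one extra data point weighted by
    its occupancy.  The returned curve is clamped below at
    ``sigma_floor = max(1e-4, 1e-3 * median smoothed sd)``.
    """
    if stats.smoothed_sigma is None:
        raise ValidationError("smooth_bin_sigmas must be applied before fitting")
    x = stats.mu.astype(np.float64)
    y = stats.smoothed_sigma.astype(np.float64)
    w = stats.count.astype(np.float64)
    if stats.has_zero_bin:
        x = np.concatenate([[stats.zero_mu], x])
        y = np.concatenate([[stats.zero_sigma], y])
        w = np.concatenate([[stats.zero_count], w])

    order = np.argsort(x, kind="stable")
    x, y, w = x[order], y[order], w[order]
    # merge duplicate abscissae by weighted average (spline needs strict increase)
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        wsum = np.bincount(inv, weights=w)
        ysum = np.bincount(inv, weights=w * y)
        x, y, w = ux, ysum / wsum, wsum
    if len(x) < MIN_SPLINE_POINTS:
        raise ValidationError(
            f"spline fit needs at least {MIN_SPLINE_POINTS} distinct bin means, got {len(x)}"
        )

    lam = None if (cv and p_override is None) else p_override
    spline = make_smoothing_spline(x, y, w=w / w.mean(), lam=lam)
    sigma_floor = max(1e-4, 1e-3 * float(np.median(stats.smoothed_sigma)))
    meta = dict(metadata or {})
    meta.setdefault("b", stats.b)
    meta["smoothing_parameter"] = p_override
    curve = MeanVarianceCurve(spline, float(x[0]), float(x[-1]), sigma_floor, meta)
    return curve


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

def select_hyperparameters(
    reps: ReplicateSet,
    grid=None,
    train_chroms=None,
    test_chroms=None,
    metric_bin_size: int = 10_000,
    zero_bin: Optional[bool] = None,
):
    """Grid search over (b, beta) scored on held-out chromosomes.

    For each candidate the curve is trained on ``train_chroms`` and scored
    on ``test_chroms`` by the Gaussian quality-of-fit log likelihood (the
    selection objective) and the variance-instability of the resulting
    transform.  Returns ``(b, beta, report)`` with the full score table.
    """
    import pandas as pd

    from .metrics import gaussian_fit_loglik, variance_instability
    from .transform import build_vss_transform

    if grid is None:
        grid = [(100_000, 1e3), (1_000, 1e7)]
    grid = list(grid)
    if not grid:
        raise ValidationError("hyperparameter grid must be non-empty")
    if train_chroms is not None and test_chroms is not None:
        if set(train_chroms) & set(test_chroms):
            raise ValidationError("train and test chromosomes must be disjoint")
    if zero_bin is None:
        zero_bin = default_hyperparameters(reps.signal_type)[2]

    train = reps.filter_chroms(train_chroms) if train_chroms is not None else reps
    test = reps.filter_chroms(test_chroms) if test_chroms is not None else reps

    rows = []
    for b, beta in grid:
        b = int(b)
        stats = compute_bin_stats(build_base_aux(train), b, zero_bin=zero_bin)
        stats = smooth_bin_sigmas(stats, beta)
        curve = fit_sigma_curve(stats, metadata={"beta": beta})
        pairs = build_base_aux(test)
        fit = gaussian_fit_loglik(pairs, curve, sigma_source=f"vss(b={b}, beta={beta:g})")
        model = build_vss_transform(curve)
        inst = variance_instability(model(pairs.base), model(pairs.aux), b=metric_bin_size)
        rows.append(
            {
                "b": b,
                "beta": beta,
                "mean_log_density": fit.mean_log_density,
                "variance_instability": inst.score,
            }
        )
    report = pd.DataFrame(rows)
    best = report["mean_log_density"].idxmax()
    return int(report.loc[best, "b"]), float(report.loc[best, "beta"]), report
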