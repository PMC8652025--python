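"""Variance-stabilizing and alternative signal transformations.

Given a mean–variance curve ``sigma_hat(mu)``, the variance-stabilizing
transform is the antiderivative of its reciprocal::

    t(x) = integral_0^x  du / sigma_hat(u)

so that, to first order, ``var(t(x_i))`` is constant across positions
regardless of ``mu_i``.  The classical alternatives are special cases:
``log(x + c)`` stabilizes data with ``sigma(mu) ∝ mu + c`` and
``asinh(x)`` data with ``sigma(mu) ∝ sqrt(mu**2 + 1)``.

Every transform can also report the mean–variance relationship it
*implicitly assumes*: ``sigma_tilde(u) = 1 / t'(u)``, the reciprocal of
its derivative.  This is what the quality-of-fit metric evaluates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ValidationError, VssError
from .mv_curve import MeanVarianceCurve
from .signal_io import SignalTrack

KINDS = ("vss", "log_offset", "log_affine", "asinh", "identity")


@dataclass
class TransformModel:
    """A strictly increasing signal transformation ``t(x)``.

    For ``kind='vss'`` the transform is a monotone piecewise-linear
    interpolant of a numeric integration grid ``(x, t(x))`` on
    ``[0, x_max]``, extended linearly with slope ``1/sigma_hat(x_max)``
    above and reflected with the left boundary slope below 0.  The analytic
    kinds (``log_offset``, ``log_affine``, ``asinh``, ``identity``) use
    closed forms.
    """

    kind: str
    params: dict = field(default_factory=dict)
    grid_x: Optional[np.ndarray] = None   # vss only
    grid_t: Optional[np.ndarray] = None   # vss only
    slope_lo: Optional[float] = None      # vss: slope used below 0
    slope_hi: Optional[float] = None      # vss: slope used above x_max
    curve: Optional[MeanVarianceCurve] = None  # provenance

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if self.kind == "vss":
            if self.grid_x is None or self.grid_t is None:
                raise ValidationError("vss transform requires a lookup grid")
            self.grid_x = np.asarray(self.grid_x, dtype=np.float64)
            self.grid_t = np.asarray(self.grid_t, dtype=np.float64)
            if np.any(np.diff(self.grid_x) <= 0) or np.any(np.diff(self.grid_t) <= 0):
                raise VssError("vss transform grid is not strictly increasing")

    # -- factory helpers ----------------------------------------------

    @classmethod
    def identity(cls) -> "TransformModel":
        return cls("identity")

    @classmethod
    def log_offset(cls, c: float = 1.0) -> "TransformModel":
        """``t(x) = log(x + c)``; assumes ``sigma(mu) ∝ mu + c``."""
        if c <= 0:
            raise ValidationError("log offset c must be positive")
        return cls("log_offset", {"c": float(c)})

    @classmethod
    def log_affine(cls, a: float = 1.0, b: float = 1.0) -> "TransformModel":
        """``t(x) = log(a*x + b)`` — the general linear-argument log."""
        if a <= 0 or b <= 0:
            raise ValidationError("log_affine requires a > 0 and b > 0")
        return cls("log_affine", {"a": float(a), "b": float(b)})

    @classmethod
    def asinh(cls) -> "TransformModel":
        """``t(x) = asinh(x)``; assumes ``sigma(mu) ∝ sqrt(mu**2 + 1)``."""
        return cls("asinh")

    # -- evaluation ---------------------------------------------------

    @property
    def x_max(self) -> Optional[float]:
        return float(self.grid_x[-1]) if self.grid_x is not None else None

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        if self.kind == "identity":
            return x.copy()
        if self.kind == "log_offset":
            return self._checked_log(x + self.params["c"], x)
        if self.kind == "log_affine":
            return self._checked_log(self.params["a"] * x + self.params["b"], x)
        if self.kind == "asinh":
            return np.arcsinh(x)
        # vss: piecewise-linear lookup with linear extensions
        out = np.interp(x, self.grid_x, self.grid_t)
        out = np.where(x > self.grid_x[-1], self.grid_t[-1] + (x - self.grid_x[-1]) * self.slope_hi, out)
        out = np.where(x < 0.0, -self.slope_lo * np.abs(x), out)
        return out

    def _checked_log(self, arg, x):
        bad = arg <= 0
        if np.any(bad):
            n_bad = int(bad.sum())
            worst = float(np.asarray(x)[bad].min()) if np.asarray(x).ndim else float(x)
            raise ValidationError(
                f"{self.kind} transform undefined for {n_bad} value(s); smallest input {worst:g}"
            )
        return np.log(arg)

    def implied_sigma(self, u):
        """Mean–variance relationship the transform implicitly assumes:
        ``sigma_tilde(u) = 1 / t'(u)``.

        For ``vss`` models the derivative comes from the interpolation
        segment containing ``u``; outside the grid the boundary slope is
        used (with a warning).
        """
        u = np.asarray(u, dtype=np.float64)
        if self.kind == "identity":
            return np.ones_like(u)
        if self.kind == "log_offset":
            return u + self.params["c"]
        if self.kind == "log_affine":
            a, b = self.params["a"], self.params["b"]
            return (a * u + b) / a
        if self.kind == "asinh":
            return np.sqrt(u ** 2 + 1.0)
        outside = (u < self.grid_x[0]) | (u > self.grid_x[-1])
        if np.any(outside):
            warnings.warn(
                f"implied_sigma evaluated outside [{self.grid_x[0]:g}, {self.grid_x[-1]:g}] "
                "for some values; boundary derivative used",
                stacklevel=2,
            )
        seg = np.clip(np.searchsorted(self.grid_x, u, side="right") - 1, 0, len(self.grid_x) - 2)
        slopes = np.diff(self.grid_t) / np.diff(self.grid_x)
        sig = 1.0 / slopes[seg]
        sig = np.where(u > self.grid_x[-1], 1.0 / self.slope_hi, sig)
        sig = np.where(u < self.grid_x[0], 1.0 / slopes[0] if self.grid_x[0] > 0 else 1.0 / self.slope_lo, sig)
        return sig


def build_vss_transform(
    curve: MeanVarianceCurve,
    x_max: Optional[float] = None,
    n_grid: int = 4096,
) -> TransformModel:
    """Numerically integrate ``1/sigma_hat`` into a monotone lookup table.

    Composite trapezoidal integration on ``n_grid`` uniformly spaced points
    from 0 to ``x_max`` (default: the curve's domain maximum), anchored at
    ``t(0) = 0``.  Above ``x_max`` the transform continues linearly with
    slope ``1/sigma_hat(x_max)``; below 0 it is reflected with slope
    ``1/sigma_hat(mu_min)``.
    """
    if n_grid < 64:
        raise ValidationError("n_grid must be at least 64")
    if x_max is None:
        x_max = max(curve.mu_max, np.finfo(float).tiny)
    if x_max < curve.mu_max:
        raise ValidationError("x_max must cover the curve domain maximum")
    if x_max <= 0:
        raise ValidationError("x_max must be positive")

    xs = np.linspace(0.0, float(x_max), int(n_grid))
    inv_sigma = 1.0 / curve(xs)
    if not np.all(np.isfinite(inv_sigma)) or np.any(inv_sigma <= 0):
        raise VssError("sigma_hat is non-positive or non-finite on the integration grid")
    ts = np.concatenate([[0.0], cumulative_trapezoid(inv_sigma, xs)])
    return TransformModel(
        kind="vss",
        grid_x=xs,
        grid_t=ts,
        slope_lo=float(1.0 / curve(curve.mu_min)),
        slope_hi=float(1.0 / curve(x_max)),
        curve=curve,
    )


def apply_transform(model: TransformModel, track: SignalTrack) -> SignalTrack:
    """Apply a transform value-wise; interval structure is preserved."""
    return track.with_values(model(track.values))


def implied_sigma(model: TransformModel, u):
    """Module-level alias for :meth:`TransformModel.implied_sigma`."""
    return model.implied_sigma(u)
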