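"""Homeostasis descriptor suite for emission chronograms.

The descriptors characterise a monitored volatile-emission time series the
way the heart-rate-variability literature characterises physiological
signals: statistical moments (non-Gaussianity), the autocorrelation function
(memory), Poincare-plot SD1/SD2 (short- vs long-term variability), the value
histogram, and the area under the curve (total production).

Conventions (fixed so the exact algebraic identities in the test suite hold):

* skewness g1 = m3 / m2^(3/2) and excess kurtosis g2 = m4 / m2^2 - 3 with
  denominator-n ("population") central moments; a Gaussian gives 0 for both.
* the ACF is the biased, demeaned estimator
  rho_k = sum_{t}(x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2,
  which guarantees |rho_k| <= 1 and rho_0 = 1.
* SD1/SD2 are population SDs (denominator n) of the scaled successive
  differences (a-b)/sqrt(2) and sums (a+b)/sqrt(2) with a = x[1:], b = x[:-1],
  so that SD1^2 + SD2^2 = Var(a) + Var(b) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .io import Chronogram

DEFAULT_MAX_LAG = 48  # two days of hourly samples
DEFAULT_N_BINS = 30


def _as_vector(x, min_n: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError(f"{what}: empty input")
    if x.size < min_n:
        raise InsufficientDataError(f"{what}: need at least {min_n} points, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise UndefinedStatisticError(f"{what}: input contains non-finite values")
    return x


def skewness(x, bias: bool = True) -> float:
    """Moment-based skewness g1 = m3/m2^(3/2) (``bias=False`` gives the
    bias-corrected G1 variant)."""
    x = _as_vector(x, 3, "skewness")
    if np.var(x) == 0:
        raise UndefinedStatisticError("skewness undefined for zero-variance input")
    return float(scipy.stats.skew(x, bias=bias))


def excess_kurtosis(x, bias: bool = True) -> float:
    """Moment-based excess kurtosis g2 = m4/m2^2 - 3 (Gaussian -> 0)."""
    x = _as_vector(x, 4, "excess_kurtosis")
    if np.var(x) == 0:
        raise UndefinedStatisticError("kurtosis undefined for zero-variance input")
    return float(scipy.stats.kurtosis(x, fisher=True, bias=bias))


def acf(x, max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Biased demeaned autocorrelation function over lags 0..max_lag."""
    x = _as_vector(x, 2, "acf")
    if max_lag < 1 or max_lag >= x.size:
        raise InsufficientDataError(
            f"max_lag must be in [1, n-1]; got {max_lag} for n={x.size}"
        )
    if np.var(x) == 0:
        raise UndefinedStatisticError("acf undefined for zero-variance input")
    return np.asarray(_sm_acf(x, nlags=max_lag, adjusted=False, fft=True), dtype=float)


class PoincareDescriptors(NamedTuple):
    sd1: float
    sd2: float
    ratio: float  # NaN when SD2 == 0 (undefined)


def poincare(x) -> PoincareDescriptors:
    """Poincare-plot descriptors of successive-point pairs (x_t, x_{t+1}).

    SD1 measures spread perpendicular to the identity line (short-term
    variability), SD2 along it (long-term variability).  The ratio SD1/SD2 is
    NaN (flagged undefined) when SD2 = 0.
    """
    x = _as_vector(x, 3, "poincare")
    a, b = x[1:], x[:-1]
    sd1 = float(np.std((a - b) / np.sqrt(2.0)))  # population SD
    sd2 = float(np.std((a + b) / np.sqrt(2.0)))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return PoincareDescriptors(sd1, sd2, ratio)


def auc(c, intensities=None) -> float:
    """Trapezoidal area under the intensity-time curve, in intensity*hours.

    Accepts a :class:`Chronogram` or ``(times, intensities)`` arrays.
    Negative intensities (possible after noise) are integrated as-is.
    """
    if isinstance(c, Chronogram):
        times, intens = c.times, c.intensities
    else:
        times = np.asarray(c, dtype=float)
        intens = np.asarray(intensities, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("auc requires at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise InsufficientDataError("auc requires strictly increasing times")
    return float(np.trapezoid(intens, times))


def histogram(x, n_bins: int = DEFAULT_N_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram spanning [min, max]; rightmost bin closed.

    Returns ``(edges, counts)`` with ``counts.sum() == len(x)``.
    """
    x = _as_vector(x, 1, "histogram")
    if n_bins < 1:
        raise InsufficientDataError("n_bins must be >= 1")
    counts, edges = np.histogram(x, bins=n_bins)
    return edges, counts


@dataclass
class DescriptorSet:
    """The full descriptor suite for one chronogram.

    Any statistic that could not be computed is NaN (or ``None`` for the
    ACF/histogram) with the reason recorded in ``failures``.
    """

    n_points: int
    mean_intensity: float
    skewness: float
    excess_kurtosis: float
    acf: np.ndarray | None
    sd1: float
    sd2: float
    sd_ratio: float
    auc: float
    histogram_edges: np.ndarray | None
    histogram_counts: np.ndarray | None
    condition: str = ""
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def acf1(self) -> float:
        """Lag-1 autocorrelation (NaN if the ACF failed)."""
        return float(self.acf[1]) if self.acf is not None and len(self.acf) > 1 else float("nan")


def describe(
    c: Chronogram,
    max_lag: int = DEFAULT_MAX_LAG,
    n_bins: int = DEFAULT_N_BINS,
) -> DescriptorSet:
    """Compute every descriptor for one chronogram, collecting partial failures.

    A degenerate input (e.g. a constant chronogram) does not abort the whole
    set: the statistics that remain well defined (mean, AUC, histogram) are
    reported and each failed one is recorded in ``failures`` by name.
    """
    x = c.intensities
    failures: dict[str, str] = {}

    def attempt(name, fn, default=float("nan")):
        try:
            return fn()
        except Exception as exc:  # collected, not raised: partial-failure contract
            failures[name] = f"{type(exc).__name__}: {exc}"
            return default

    skew = attempt("skewness", lambda: skewness(x))
    kurt = attempt("excess_kurtosis", lambda: excess_kurtosis(x))
    acf_v = attempt("acf", lambda: acf(x, max_lag=min(max_lag, x.size - 1) or 1), None)
    poin = attempt("poincare", lambda: poincare(x), None)
    area = attempt("auc", lambda: auc(c))
    hist = attempt("histogram", lambda: histogram(x, n_bins=n_bins), None)
    return DescriptorSet(
        n_points=c.n,
        mean_intensity=float(np.mean(x)),
        skewness=skew,
        excess_kurtosis=kurt,
        acf=acf_v,
        sd1=poin.sd1 if poin else float("nan"),
        sd2=poin.sd2 if poin else float("nan"),
        sd_ratio=poin.ratio if poin else float("nan"),
        auc=area,
        histogram_edges=hist[0] if hist else None,
        histogram_counts=hist[1] if hist else None,
        condition=c.condition,
        failures=failures,
    )
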