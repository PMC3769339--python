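"""Lapse-aware Weibull psychometric model for 2AFC discrimination.

Discrimination performance — the probability of choosing the higher of two
sugar concentrations in a two-alternative forced-choice (2AFC) task — is
modelled as

    Psi(i) = 0.5 + (0.5 - lapse/2) * F(i; m, s)

where ``i`` is the (near-miss) relative intensity of the pair, ``F`` is a
Weibull sigmoid re-parameterised by its threshold ``m`` (``F(m) = 0.5``) and
the slope ``s`` of ``F`` at the threshold, and ``lapse`` is the lapse rate:
the probability of responding without regard to the stimuli.  The curve runs
from chance (0.5 at zero intensity) to an upper asymptote of ``1 - lapse/2``;
at ``i = m`` it passes exactly through the midpoint ``0.75 - lapse/4``
(75% when the lapse rate is zero).

Slope convention: ``s`` is the derivative of the *unscaled* sigmoid ``F`` at
``m``; the observable performance curve's slope at threshold is therefore
``(0.5 - lapse/2) * s``.  Both readings are recoverable from the stored
parameter tuple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .intensity import intensity_peak_location, near_miss_intensity

__all__ = [
    "PsychometricParams",
    "sigmoid_core",
    "sigmoid_core_inverse",
    "predict_performance",
    "predict_at_intensity",
    "intensity_at_performance",
    "preference_curve",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the near-miss Weibull psychometric function.

    Attributes
    ----------
    m : float
        Threshold, in scaled-intensity units: the intensity at which the
        curve is halfway between chance and its upper asymptote.
    s : float
        Slope of the unscaled sigmoid at the threshold, per scaled-intensity
        unit.
    lapse : float
        Lapse rate in ``[0, 0.5)``; the upper asymptote is ``1 - lapse/2``.
    beta : float
        Near-miss exponent; 1 corresponds to Weber's law.
    scale : float
        Intensity display factor applied inside the near-miss intensity.
    """

    m: float
    s: float
    lapse: float = 0.0
    beta: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise DomainError(f"threshold m={self.m} must be positive")
        if self.s <= 0:
            raise DomainError(f"slope s={self.s} must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise DomainError(f"lapse rate {self.lapse} must lie in [0, 0.5)")
        if self.scale <= 0:
            raise DomainError(f"scale={self.scale} must be positive")
        if not all(map(math.isfinite, (self.m, self.s, self.lapse, self.beta, self.scale))):
            raise DomainError("parameters must be finite")

    @property
    def upper_asymptote(self) -> float:
        return 1.0 - self.lapse / 2.0

    @property
    def shape(self) -> float:
        """Weibull shape ``k = 2 m s / ln 2`` implied by (m, s)."""
        return 2.0 * self.m * self.s / _LN2

    @property
    def weibull_scale(self) -> float:
        """Weibull scale ``lambda = m * (ln 2)**(-1/k)`` implied by (m, s)."""
        return self.m * _LN2 ** (-1.0 / self.shape)

    def with_(self, **changes) -> "PsychometricParams":
        return replace(self, **changes)


def sigmoid_core(i, m: float, s: float):
    """Weibull sigmoid ``F(i) = 1 - exp(-(i/lambda)**k)`` on intensity ``i >= 0``.

    Parameterised so that ``F(0) = 0``, ``F(m) = 0.5`` exactly and
    ``dF/di(m) = s``: shape ``k = 2 m s / ln 2`` and scale
    ``lambda = m (ln 2)**(-1/k)``.  Accepts scalars or arrays.
    """
    if m <= 0 or s <= 0:
        raise DomainError(f"threshold m={m} and slope s={s} must be positive")
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0):
        raise DomainError("intensity must be non-negative")
    k = 2.0 * m * s / _LN2
    lam = m * _LN2 ** (-1.0 / k)
    out = -np.expm1(-((arr / lam) ** k))
    return float(out) if np.isscalar(i) or arr.ndim == 0 else out


def sigmoid_core_inverse(f: float, m: float, s: float) -> float:
    """Inverse of :func:`sigmoid_core`: the intensity with ``F(i) = f``."""
    if m <= 0 or s <= 0:
        raise DomainError(f"threshold m={m} and slope s={s} must be positive")
    if not 0.0 <= f < 1.0:
        raise DomainError(f"sigmoid value {f} must lie in [0, 1)")
    k = 2.0 * m * s / _LN2
    lam = m * _LN2 ** (-1.0 / k)
    return lam * (-math.log1p(-f)) ** (1.0 / k)


def predict_at_intensity(i, params: PsychometricParams):
    """Performance ``0.5 + (0.5 - lapse/2) F(i)`` at scaled intensity ``i``."""
    f = sigmoid_core(i, params.m, params.s)
    return 0.5 + (0.5 - params.lapse / 2.0) * f


def predict_performance(x: float, a: float, params: PsychometricParams) -> float:
    """Predicted probability of choosing the higher of concentrations x and a.

    The pair is ordered internally, so arguments may come in either order;
    the returned probability always refers to the higher-concentration
    option and lies in ``[0.5, 1 - lapse/2)``.  Equal concentrations give
    exactly 0.5 (chance).
    """
    hi, lo = (x, a) if x >= a else (a, x)
    i = near_miss_intensity(hi, lo, params.beta, params.scale)
    return float(predict_at_intensity(i, params))


def intensity_at_performance(p: float, params: PsychometricParams) -> float:
    """Scaled intensity at which the model predicts performance ``p``.

    ``p`` must lie in the attainable band ``[0.5, 1 - lapse/2)``.  Round-trips
    with :func:`predict_at_intensity` to ~1e-9 relative accuracy.
    """
    upper = params.upper_asymptote
    if not 0.5 <= p < upper:
        raise DomainError(
            f"performance {p} outside attainable interval [0.5, {upper})"
        )
    f = (p - 0.5) / (0.5 - params.lapse / 2.0)
    return sigmoid_core_inverse(f, params.m, params.s)


def preference_curve(
    standard: float,
    alternatives: Iterable[float],
    params: PsychometricParams,
) -> pd.DataFrame:
    """Predicted preference for each alternative over a fixed standard.

    For alternatives above the standard the preference is the predicted
    probability of choosing the alternative; below the standard it is one
    minus the probability of choosing the standard, so the curve passes
    through 0.5 at the standard and approaches ``lapse/2`` far below and
    ``1 - lapse/2`` far above it.

    Returns a DataFrame with columns ``alternative_conc`` and ``preference``.
    """
    if standard <= 0:
        raise DomainError(f"standard concentration {standard} must be positive")
    alts = [float(c) for c in alternatives]
    prefs = []
    for alt in alts:
        if alt <= 0:
            raise DomainError(f"alternative concentration {alt} must be positive")
        if alt == standard:
            prefs.append(0.5)
        elif alt > standard:
            prefs.append(predict_performance(alt, standard, params))
        else:
            prefs.append(1.0 - predict_performance(standard, alt, params))
    return pd.DataFrame({"alternative_conc": alts, "preference": prefs})


def performance_peak_concentration(a: float, params: PsychometricParams) -> float | None:
    """Test concentration at which predicted performance peaks, if any.

    Performance is monotone in intensity, so for ``beta > 1`` it inherits the
    interior intensity peak at ``a (beta + 1) / (beta - 1)``; for
    ``beta <= 1`` it is non-decreasing in the test concentration.
    """
    return intensity_peak_location(a, params.beta)
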