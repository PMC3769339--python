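"""Stimulus-intensity arithmetic for sugar-concentration discrimination.

The perceptual "distance" between two sugar concentrations is expressed as a
Weber-type ratio.  For two concentrations ``x`` and ``a`` (in % weight/weight)
the *relative intensity* is

    i(x, a) = |x - a| / ((x + a) / 2)

a symmetric, standard-free analogue of the Weber fraction ``delta / a``.  The
*near-miss* generalisation raises the mean-magnitude term to an exponent
``beta``:

    i_beta(x, a) = scale * |x - a| / ((x + a) / 2) ** beta

``beta = 1`` recovers plain relative intensity (Weber's law); ``beta > 1``
strengthens and ``beta < 1`` weakens the magnitude effect.  ``scale`` is a
pure display/scaling factor that keeps intensities of order one when ``beta``
moves the denominator over several decades; it is mathematically redundant
with the threshold of any psychometric model applied downstream.

The module also provides sugar-solution unit conversions (molarity to mass
fraction and mass fraction to molar sucrose equivalents) built on a
polynomial model of aqueous-sucrose density at 20 degrees C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = [
    "ConcentrationPair",
    "WeberFraction",
    "weber_fraction",
    "relative_intensity",
    "near_miss_intensity",
    "intensity_peak_location",
    "sucrose_density",
    "molar_to_mass_fraction",
    "mass_fraction_to_molar",
    "mass_fraction_to_sucrose_equivalents",
    "SUCROSE_MOLAR_MASS",
    "HEXOSE_MOLAR_MASS",
    "ZERO_INTENSITY_SUBSTITUTE",
]

#: Molar mass of sucrose (C12H22O11), g/mol.
SUCROSE_MOLAR_MASS = 342.30
#: Molar mass of glucose/fructose (C6H12O6), g/mol.
HEXOSE_MOLAR_MASS = 180.16

#: Value historically substituted for an exact-zero intensity by analysis
#: scripts whose fitting routines rejected 0.  Exposed for compatibility
#: reruns; the library itself accepts exact zeros everywhere.
ZERO_INTENSITY_SUBSTITUTE = 1.0e-6

# Cubic fit of aqueous-sucrose density (g/cm^3) against mass fraction
# (% w/w) at 20 C, fitted to the CRC Handbook concentrative-properties
# table over 0-60 % w/w; max fit error 2.8e-5 g/cm^3.
_DENSITY_COEFFS = (
    0.998257664835165,
    3.843457126207042e-03,
    1.3891008991012051e-05,
    3.494172494169203e-08,
)
_DENSITY_MAX_MASS_FRACTION = 70.0
_MOLARITY_MAX = 2.5


@dataclass(frozen=True)
class ConcentrationPair:
    """An ordered pair of sugar concentrations (% w/w), higher first.

    Attributes
    ----------
    x : float
        Concentration of the higher (or equal) option.
    a : float
        Concentration of the lower option.
    """

    x: float
    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.a)):
            raise DomainError("concentrations must be finite")
        if self.a <= 0:
            raise DomainError(f"lower concentration a={self.a} must be positive")
        if self.x < self.a:
            raise DomainError(
                f"higher concentration x={self.x} must be >= lower a={self.a}"
            )

    @classmethod
    def ordered(cls, c1: float, c2: float) -> "ConcentrationPair":
        """Build a pair from two concentrations in either order."""
        return cls(max(c1, c2), min(c1, c2))


@dataclass(frozen=True)
class WeberFraction:
    """A differential threshold expressed relative to its standard.

    ``c = delta_pi / a`` is the Weber constant: the just-detectable (at
    criterion probability ``pi``) difference as a fraction of the standard
    magnitude ``a``.
    """

    a: float
    delta_pi: float
    pi: float
    c: float

    @classmethod
    def from_threshold(cls, delta_pi: float, a: float, pi: float = 0.75) -> "WeberFraction":
        if not 0.5 < pi < 1:
            raise DomainError(f"criterion probability pi={pi} must lie in (0.5, 1)")
        return cls(a=a, delta_pi=delta_pi, pi=pi, c=weber_fraction(delta_pi, a))


def weber_fraction(delta_pi: float, a: float) -> float:
    """Weber fraction ``delta_pi / a``.

    Parameters
    ----------
    delta_pi : float
        Magnitude difference (differential threshold), same units as ``a``.
    a : float
        Standard magnitude; must be positive.
    """
    if a <= 0:
        raise DomainError(f"standard magnitude a={a} must be positive")
    if delta_pi < 0:
        raise DomainError(f"difference delta_pi={delta_pi} must be non-negative")
    return delta_pi / a


def relative_intensity(x: float, a: float) -> float:
    """Relative intensity ``|x - a| / mean(x, a)``.

    Symmetric in its arguments and bounded in ``[0, 2)``.  Equals the Weber
    fraction computed with the pair mean in place of a designated standard,
    which makes it applicable when neither option is privileged.
    """
    if x <= 0:
        raise DomainError(f"concentration x={x} must be positive")
    if a <= 0:
        raise DomainError(f"concentration a={a} must be positive")
    return abs(x - a) / ((x + a) / 2.0)


def near_miss_intensity(
    x: float, a: float, beta: float = 1.0, scale: float = 1.0
) -> float:
    """Near-miss relative intensity ``scale * |x - a| / mean(x, a)**beta``.

    With ``beta = 1`` and ``scale = 1`` this is exactly
    :func:`relative_intensity`.  ``beta`` controls the strength of the
    magnitude effect relative to the distance effect.
    """
    if x <= 0:
        raise DomainError(f"concentration x={x} must be positive")
    if a <= 0:
        raise DomainError(f"concentration a={a} must be positive")
    if scale <= 0:
        raise DomainError(f"scale={scale} must be positive")
    if beta == 1.0:
        # Reduce exactly (bit-for-bit at scale 1) to the Weber form.
        return scale * relative_intensity(x, a)
    return scale * abs(x - a) / ((x + a) / 2.0) ** beta

def intensity_peak_location(a: float, beta: float) -> float | None:
    """Concentration maximising near-miss intensity against a fixed lower ``a``.

    For ``beta > 1`` the intensity ``(x - a) / ((x + a)/2)**beta`` rises and
    then falls as ``x`` grows; setting its derivative to zero gives the
    closed-form peak ``x* = a (beta + 1) / (beta - 1)``.  For ``beta <= 1``
    intensity is non-decreasing in ``x`` and there is no interior peak
    (returns ``None``).  This is why fitted discrimination curves with
    ``beta > 1`` can *decline* at very high test concentrations.
    """
    if a <= 0:
        raise DomainError(f"concentration a={a} must be positive")
    if beta <= 1.0:
        return None
    return a * (beta + 1.0) / (beta - 1.0)


def natural_scale(beta: float, standard: float = 20.0) -> float:
    """Power-of-ten display factor keeping near-miss intensities of order one.

    Raising the mean-concentration term to ``beta`` shrinks (``beta > 1``)
    or inflates (``beta < 1``) intensities by roughly ``standard**(beta-1)``
    relative to plain relative intensity.  The returned factor is the power
    of ten nearest to that ratio, so scaled intensities — and thresholds
    quoted on the scaled axis — stay commensurate across exponents (e.g. 10
    for ``beta = 2`` and 0.1 for ``beta = 0.3`` around a 20% standard).
    The factor is display-only: fitted curves are invariant to it.
    """
    if standard <= 0:
        raise DomainError(f"standard concentration {standard} must be positive")
    return 10.0 ** round((beta - 1.0) * math.log10(standard))


def sucrose_density(mass_fraction: float) -> float:
    """Density (g/L) of an aqueous sucrose solution at 20 C.

    ``mass_fraction`` is in % w/w over [0, 70].  Cubic polynomial fit of the
    CRC Handbook table; also used as a serviceable approximation for mixed
    sucrose/hexose solutions, whose densities differ by <0.5% at equal mass
    fraction.
    """
    if not 0.0 <= mass_fraction <= _DENSITY_MAX_MASS_FRACTION:
        raise DomainError(
            f"mass fraction {mass_fraction} outside density-model range "
            f"[0, {_DENSITY_MAX_MASS_FRACTION}] % w/w"
        )
    c0, c1, c2, c3 = _DENSITY_COEFFS
    return 1000.0 * (c0 + c1 * mass_fraction + c2 * mass_fraction**2 + c3 * mass_fraction**3)


def molar_to_mass_fraction(molarity: float) -> float:
    """Convert sucrose molarity (mol/L) to mass fraction (% w/w).

    Solves ``c = 100 * molarity * M_sucrose / rho(c)`` self-consistently by
    fixed-point iteration (the map is a strong contraction because density
    varies slowly with ``c``).  Monotone increasing in ``molarity``.
    """
    if not 0.0 <= molarity <= _MOLARITY_MAX:
        raise DomainError(
            f"molarity {molarity} outside supported range [0, {_MOLARITY_MAX}] mol/L"
        )
    if molarity == 0.0:
        return 0.0
    grams_per_litre = molarity * SUCROSE_MOLAR_MASS
    c = 10.0
    for _ in range(200):
        c_next = 100.0 * grams_per_litre / sucrose_density(min(c, _DENSITY_MAX_MASS_FRACTION))
        if abs(c_next - c) < 1e-12:
            return c_next
        c = c_next
    return c


def mass_fraction_to_molar(mass_fraction: float) -> float:
    """Convert sucrose mass fraction (% w/w) to molarity (mol/L)."""
    if not 0.0 <= mass_fraction <= _DENSITY_MAX_MASS_FRACTION:
        raise DomainError(
            f"mass fraction {mass_fraction} outside supported range "
            f"[0, {_DENSITY_MAX_MASS_FRACTION}] % w/w"
        )
    return mass_fraction / 100.0 * sucrose_density(mass_fraction) / SUCROSE_MOLAR_MASS


def mass_fraction_to_sucrose_equivalents(
    c: float,
    composition: dict[str, float] | None = None,
) -> float:
    """Express a mixed-sugar solution as mmol/L sucrose equivalents.

    Convention: *mass-based* equivalence — one gram of hexose counts as one
    gram of sucrose, so the sucrose-equivalent molarity is the total sugar
    mass per litre divided by the sucrose molar mass.  Under this convention
    a 20% w/w solution maps to ~632 mmol/L and 50% to ~1796 mmol/L
    regardless of the sucrose/hexose split.  Solution density is taken from
    the sucrose model at the same total mass fraction.

    Parameters
    ----------
    c : float
        Total sugar concentration, % w/w, in (0, 70].
    composition : dict, optional
        Mass fractions of ``{"sucrose", "glucose", "fructose"}`` summing to
        one.  Defaults to equal thirds (the hexose:sucrose ratio typical of
        bat-pollinated-plant nectar).  Validated, although the mass-based
        convention makes the result composition-independent.
    """
    if not 0.0 <= c <= _DENSITY_MAX_MASS_FRACTION:
        raise DomainError(
            f"concentration {c} outside supported range (0, {_DENSITY_MAX_MASS_FRACTION}] % w/w"
        )
    if composition is None:
        composition = {"sucrose": 1 / 3, "glucose": 1 / 3, "fructose": 1 / 3}
    unknown = set(composition) - {"sucrose", "glucose", "fructose"}
    if unknown:
        raise DomainError(f"unknown sugars in composition: {sorted(unknown)}")
    values = list(composition.values())
    if any(v < 0 for v in values):
        raise DomainError("composition mass fractions must be non-negative")
    total = sum(values)
    if abs(total - 1.0) > 1e-9:
        raise DomainError(f"composition mass fractions sum to {total}, expected 1")
    grams_sugar_per_litre = c / 100.0 * sucrose_density(c)
    return grams_sugar_per_litre / SUCROSE_MOLAR_MASS * 1000.0
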