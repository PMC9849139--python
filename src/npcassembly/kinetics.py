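"""Two-component kinetic model of nuclear pore complex (NPC) assembly.

After an open mitosis, NPCs form through two concurrent pathways: a fast
postmitotic pathway that dominates the peripheral ("non-core") nuclear
envelope, and a slow interphase pathway that dominates the central ("core")
region.  The observed, normalized nuclear-envelope fluorescence of a
nucleoporin (Nup) in each region is modelled as a linear mixture of the two
underlying assembly curves::

    n(t) = f_n * pm(t) + (1 - f_n) * ip(t)        (non-core)
    c(t) = f_c * pm(t) + (1 - f_c) * ip(t)        (core)

where ``f_n`` and ``f_c`` are the postmitotic fractions of the two regions
and each underlying curve is a delayed Hill sigmoid

    pm(t) = (t - d)^n_p / ((t - d)^n_p + K_p^n_p)    for t >= d, else 0

(and analogously ``ip`` with ``n_i``, ``K_i``).  ``K`` is the median
assembly time -- the time after initiation at which half of the binding
events have occurred -- and ``n`` the Hill exponent (cooperativity).  The
initiation delay ``d`` is 0 in the non-core region and ``d_c >= 0`` in the
core region.

Because the mixture is linear, the underlying curves can be recovered
algebraically ("unmixed") from the two observed regional curves:

    ip(t) = (f_n c(t) - f_c n(t)) / (f_n - f_c)
    pm(t) = ((1 - f_c) n(t) - (1 - f_n) c(t)) / (f_n - f_c)

All quantities here are dimensionless fractions on a time grid in minutes;
copy-number amplitudes are applied downstream (see
:mod:`npcassembly.stoichiometry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "NupKinetics",
    "MixingParams",
    "AssemblyCurvePair",
    "InvalidParameterError",
    "DegenerateMixingError",
    "hill_curve",
    "mix_curves",
    "mix_forward",
    "unmix",
]


class InvalidParameterError(ValueError):
    """A kinetic or mixing parameter violates its domain constraint."""


class DegenerateMixingError(ValueError):
    """Unmixing is undefined because the two regions have equal fractions."""


@dataclass(frozen=True)
class NupKinetics:
    """Hill-curve parameters of one Nup for both assembly pathways.

    Parameters
    ----------
    nup_id : str
        Label of the nucleoporin (e.g. ``"Nup107"``).
    n_p, K_p : float
        Hill exponent and median assembly time (min) of the postmitotic
        pathway.
    n_i, K_i : float
        Hill exponent and median assembly time (min) of the interphase
        pathway.
    """

    nup_id: str
    n_p: float
    K_p: float
    n_i: float
    K_i: float

    def __post_init__(self) -> None:
        for name in ("n_p", "K_p", "n_i", "K_i"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name} must be positive and finite, got {value!r}"
                    f" for {self.nup_id}"
                )


@dataclass(frozen=True)
class MixingParams:
    """Regional mixing fractions and initiation delays.

    ``f_n`` (``f_c``) is the fraction of postmitotic assembly in the
    non-core (core) region; unmixing requires ``f_n != f_c`` and the
    convention here is ``0 <= f_c < f_n <= 1``.  The non-core delay ``d_n``
    is fixed at 0; the core region may start later (``d_c >= 0``, minutes)
    because spindle microtubules initially occupy the chromatin surface.
    """

    f_n: float
    f_c: float
    d_c: float = 0.0
    d_n: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.f_n == self.f_c:
            raise DegenerateMixingError(
                f"f_n == f_c == {self.f_n}: the regional mixture cannot be inverted"
            )
        if not (0.0 <= self.f_c < self.f_n <= 1.0):
            raise InvalidParameterError(
                f"require 0 <= f_c < f_n <= 1, got f_n={self.f_n}, f_c={self.f_c}"
            )
        if self.d_n != 0.0:
            raise InvalidParameterError("the non-core delay d_n is fixed at 0")
        if self.d_c < 0:
            raise InvalidParameterError(f"d_c must be >= 0, got {self.d_c}")


@dataclass(frozen=True)
class AssemblyCurvePair:
    """Postmitotic and interphase assembly fractions on a common time grid."""

    t: np.ndarray
    pm: np.ndarray
    ip: np.ndarray


def hill_curve(t, n: float, K: float, d: float = 0.0) -> np.ndarray:
    """Delayed Hill sigmoid ``(t-d)^n / ((t-d)^n + K^n)``, 0 for ``t <= d``.

    Evaluated in log space (``expit(n * (log(t-d) - log K))``) so that large
    exponents neither overflow nor lose the strict monotonicity in ``t``.
    At ``t == d`` the left-limit value 0 is returned.
    """
    if n <= 0 or K <= 0:
        raise InvalidParameterError(f"Hill parameters must be positive (n={n}, K={K})")
    t = np.asarray(t, dtype=float)
    dt = t - d
    out = np.zeros_like(dt)
    pos = dt > 0
    with np.errstate(divide="ignore"):
        out[pos] = expit(n * (np.log(dt[pos]) - np.log(K)))
    if out.ndim == 0:
        return float(out)
    return out


def mix_curves(pm, ip, f: float):
    """Convex combination ``f * pm + (1 - f) * ip`` of two assembly curves."""
    return f * np.asarray(pm, float) + (1.0 - f) * np.asarray(ip, float)


def mix_forward(kin: NupKinetics, mix: MixingParams, t) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: observed (non-core, core) curves for one Nup.

    Both mixture components use the region-specific initiation delay
    (``d_n = 0`` in the non-core region, ``d_c`` in the core region).
    """
    t = np.asarray(t, dtype=float)
    pm_n = hill_curve(t, kin.n_p, kin.K_p, mix.d_n)
    ip_n = hill_curve(t, kin.n_i, kin.K_i, mix.d_n)
    pm_c = hill_curve(t, kin.n_p, kin.K_p, mix.d_c)
    ip_c = hill_curve(t, kin.n_i, kin.K_i, mix.d_c)
    return mix_curves(pm_n, ip_n, mix.f_n), mix_curves(pm_c, ip_c, mix.f_c)


def unmix(n_curve, c_curve, mix: MixingParams, t=None) -> AssemblyCurvePair:
    """Algebraic inverse of the regional mixture.

    Solves the 2x2 linear system per time point; no smoothing is applied, so
    noise in the inputs propagates linearly to the outputs.  Raises
    :class:`DegenerateMixingError` when ``f_n == f_c`` (the constructor of
    :class:`MixingParams` already forbids this, but curves unmixed with
    externally supplied fractions go through the same guard).
    """
    n_curve = np.asarray(n_curve, dtype=float)
    c_curve = np.asarray(c_curve, dtype=float)
    denom = mix.f_n - mix.f_c
    if denom == 0:
        raise DegenerateMixingError("f_n == f_c: the mixing matrix is singular")
    ip = (mix.f_n * c_curve - mix.f_c * n_curve) / denom
    pm = ((1.0 - mix.f_c) * n_curve - (1.0 - mix.f_n) * c_curve) / denom
    if t is None:
        t = np.arange(n_curve.size, dtype=float)
    return AssemblyCurvePair(t=np.asarray(t, float), pm=pm, ip=ip)
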