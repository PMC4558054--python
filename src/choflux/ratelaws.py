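"""Kinetic rate-law primitives for the CHO cell metabolic model.

All reaction rates in the model are built from four mechanistic pieces:

* multiplicative Michaelis-Menten saturation in each substrate,
* saturation in a nucleotide ratio (AMP/ATP, ADP/ATP, NAD/NADH, ...),
* non-competitive inhibition, and
* non-essential activation (Segel-type: the reaction proceeds without the
  activator but is accelerated, or decelerated, in its presence).

Concentrations are mM for extracellular species and mmol per 10^6 cells for
intracellular pools; fluxes are mmol (10^6 cells)^-1 h^-1. Negative
concentrations (transient stiff-solver overshoot) are clamped to zero.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InvalidParameterError",
    "mm_term",
    "noncompetitive_inhibition_rate",
    "inhibition_factor",
    "nonessential_activation_rate",
    "activation_core",
    "ratio_term",
]


class InvalidParameterError(ValueError):
    """A kinetic constant violates its positivity constraint."""


def _clamp(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def mm_term(S, Km):
    """Michaelis-Menten saturation fraction ``S / (S + Km)``.

    Parameters
    ----------
    S : float or ndarray
        Substrate concentration (clamped to 0 if negative).
    Km : float
        Half-saturation constant, same units as ``S``; must be > 0.

    Returns
    -------
    Dimensionless fraction in [0, 1).
    """
    if np.any(np.asarray(Km) <= 0):
        raise InvalidParameterError(f"Km must be positive, got {Km}")
    S = _clamp(S)
    return S / (S + Km)


def noncompetitive_inhibition_rate(Vmax, S, Km, I, KI):
    """Inhibited Michaelis-Menten rate, ``Vmax*S / (S + Km*(1 + I/KI))``.

    The inhibitor raises the apparent half-saturation constant; with
    ``I = 0`` the plain Michaelis-Menten rate is recovered, and the rate
    decreases monotonically to 0 as ``I`` grows.
    """
    if np.any(np.asarray(Km) <= 0) or np.any(np.asarray(KI) <= 0):
        raise InvalidParameterError("Km and KI must be positive")
    S = _clamp(S)
    I = _clamp(I)
    return Vmax * S / (S + Km * (1.0 + I / KI))


def inhibition_factor(I, KI):
    """Separable non-competitive inhibition factor ``1 / (1 + I/KI)``.

    This is the multiplicative form used when wiring inhibition into
    multi-substrate reaction rates (and the quantity reported as an
    "inhibition term" time course); it lies in (0, 1].
    """
    if np.any(np.asarray(KI) <= 0):
        raise InvalidParameterError("KI must be positive")
    return 1.0 / (1.0 + _clamp(I) / KI)


def nonessential_activation_rate(Vmax, S, KS, A, KA, alpha, beta):
    """Non-essential activation rate law.

    ``V = Vmax*S*(1 + beta*A/(alpha*KA)) / (KS*(1 + A/KA) + S*(1 + A/(alpha*KA)))``

    With no activator (``A = 0``) this is plain Michaelis-Menten; with
    ``alpha = beta = 1`` activation is neutral and the Michaelis-Menten
    rate is recovered for any ``A``.
    """
    return Vmax * activation_core(S, KS, A, KA, alpha, beta)


def activation_core(S, KS, A, KA, alpha, beta):
    """Saturation fraction of the non-essential activation law (rate / Vmax)."""
    if np.any(np.asarray(KS) <= 0) or np.any(np.asarray(KA) <= 0):
        raise InvalidParameterError("KS and KA must be positive")
    if np.any(np.asarray(alpha) <= 0):
        raise InvalidParameterError("alpha must be strictly positive")
    if np.any(np.asarray(beta) < 0):
        raise InvalidParameterError("beta must be non-negative")
    S = _clamp(S)
    A = _clamp(A)
    num = S * (1.0 + beta * A / (alpha * KA))
    den = KS * (1.0 + A / KA) + S * (1.0 + A / (alpha * KA))
    return num / den


def ratio_term(numerator, denominator, K):
    """Saturation in a nucleotide pool ratio: ``r / (r + K)``, r = num/den.

    A vanishing denominator pool with a positive numerator is treated as
    saturating (the term tends to 1); if both pools vanish the term is 0.
    """
    if np.any(np.asarray(K) <= 0):
        raise InvalidParameterError("K must be positive")
    num = _clamp(numerator)
    den = _clamp(denominator)
    num, den = np.broadcast_arrays(num, den)
    out = np.where(
        den > 0.0,
        num / np.maximum(num + np.asarray(K) * den, 1e-300),
        np.where(num > 0.0, 1.0, 0.0),
    )
    if out.ndim == 0:
        return float(out)
    return out
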