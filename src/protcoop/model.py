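"""Rate functions and the right-hand side of the coculture ODE system.

The model couples two isogenic *B. subtilis* lineages — a protease
producer ``W`` and a non-producer ``C`` — to two nutrient pools and the
shared enzyme:

.. math::

    W'  &= \\max\\{0,\\; \\gamma_A g(A) + \\gamma_{Bd} g(Bd) - \\chi f(E)\\}\\,W
           - s(A+Bd)\\,W \\\\
    C'  &= [\\gamma_A g(A) + \\gamma_{Bd} g(Bd)]\\,C - s(A+Bd)\\,C \\\\
    W_s' &= s(A+Bd)\\,W \\qquad C_s' = s(A+Bd)\\,C \\\\
    B'  &= -h(B, E) \\qquad Bd' = h(B, E) - g(Bd)(W+C) \\\\
    A'  &= -g(A)(W+C) \\qquad E' = f(E)\\,W

with nutrient uptake ``g`` (Hill, coefficient 2), sporulation ``s``
(decreasing Hill), self-limiting protease production ``f`` (linear in
``E``) and Michaelis–Menten enzymatic degradation ``h``.

Only the producer pays the production cost ``chi*f(E)``, and only its
net growth term (growth minus cost, before sporulation) is clamped at
zero — the model has no death phase, so a production cost exceeding the
available growth stalls division rather than shrinking the population.
Sporulation is subtracted outside the clamp and remains active at low
nutrient, so ``W`` can still decline while spores form.
"""

from __future__ import annotations

import numpy as np

from .parameters import N_STATE, ModelParameters

__all__ = [
    "consumption_rate",
    "sporulation_rate",
    "protease_production_rate",
    "degradation_rate",
    "rhs",
    "growth_rate",
]


def _check_nonnegative(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be nonnegative; got {value!r}")


def consumption_rate(X, params: ModelParameters):
    """Per-cell nutrient uptake rate ``g(X) = k1 X^2 / (k2^2 + X^2)``.

    A Hill function with coefficient 2: zero at ``X = 0``, half-maximal
    at ``X = k2``, saturating at ``k1``.  Accepts scalars or arrays.
    """
    _check_nonnegative("nutrient abundance X", X)
    return _g(np.asarray(X, dtype=float), params.k1, params.k2)


def sporulation_rate(X, params: ModelParameters):
    """Sporulation rate ``s(X) = k3 (1 - X^2/(k4^2 + X^2))``.

    ``X`` is the total growth-supporting nutrient ``A + Bd``.  The rate
    decreases from its maximum ``k3`` at nutrient exhaustion to zero as
    nutrient becomes abundant, half-maximal at ``X = k4``.
    """
    _check_nonnegative("nutrient abundance X", X)
    X = np.asarray(X, dtype=float)
    return params.k3 * (1.0 - X * X / (params.k4**2 + X * X))


def protease_production_rate(E, params: ModelParameters):
    """Per-producer protease production rate ``f(E) = k5 (1 - E/k6)``.

    Self-limiting: maximal (``k5``) at ``E = 0`` and zero at the
    carrying capacity ``E = k6``.  Evaluated as written — callers must
    supply ``E(0) <= k6``; the ODE never leaves ``[0, k6]`` from
    admissible starts, and clamping here would mask configuration
    errors.
    """
    _check_nonnegative("protease abundance E", E)
    return params.k5 * (1.0 - np.asarray(E, dtype=float) / params.k6)


def degradation_rate(B, E, params: ModelParameters):
    """Enzymatic conversion rate of B to Bd: ``h(B,E) = k7 B E / (k8 + B)``.

    Michaelis–Menten in the substrate ``B``, first order in the enzyme
    ``E``; zero when either is absent.
    """
    _check_nonnegative("polymeric nutrient B", B)
    _check_nonnegative("protease abundance E", E)
    B = np.asarray(B, dtype=float)
    return params.k7 * B * np.asarray(E, dtype=float) / (params.k8 + B)


def growth_rate(A, Bd, params: ModelParameters):
    """Specific growth rate ``gamma_A g(A) + gamma_Bd g(Bd)`` (no cost)."""
    return params.gamma_A * consumption_rate(A, params) + params.gamma_Bd * consumption_rate(Bd, params)


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivative of the state ``(W, C, Ws, Cs, B, Bd, A, E)``.

    Validates nonnegativity of the state; the solver uses the unchecked
    :func:`_rhs_unchecked` internally so that harmless sub-tolerance
    undershoots during integration do not abort a run.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},); got {y.shape}")
    _check_nonnegative("state", y)
    return _rhs_unchecked(y, params)


# -- unchecked kernels used by the integrator --------------------------------


def _g(X, k1, k2):
    return k1 * X * X / (k2 * k2 + X * X)


def _rhs_unchecked(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    W, C, Ws, Cs, B, Bd, A, E = y
    gA = _g(A, p.k1, p.k2)
    gBd = _g(Bd, p.k1, p.k2)
    growth = p.gamma_A * gA + p.gamma_Bd * gBd
    nut = A + Bd
    spor = p.k3 * (1.0 - nut * nut / (p.k4**2 + nut * nut))
    fE = p.k5 * (1.0 - E / p.k6)
    hBE = p.k7 * B * E / (p.k8 + B)
    dW = max(0.0, growth - p.chi * fE) * W - spor * W
    dC = growth * C - spor * C
    return np.array(
        [
            dW,
            dC,
            spor * W,
            spor * C,
            -hBE,
            hBE - gBd * (W + C),
            -gA * (W + C),
            fE * W,
        ]
    )
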