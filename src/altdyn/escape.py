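"""Closed-form single-match escape probabilities and their capacity bound.

A viral strain contacting ``S`` susceptible hosts fails to generate any
single-match escape at a given contact either by triggering spacer
acquisition (probability ``q``) or by lysing with none of its ``beta``
offspring mutating the focal protospacer (probability
``(1-q)*(1-mu)**beta``).  Hence

    P_S(ne >= 1) = 1 - (q + (1-q)*(1-mu)**beta)**S,

which is bounded by its value at ``S = K``, since host density-dependent
competition caps the susceptible biomass at the carrying capacity.  Escapes
here are counted at one focal protospacer per offspring (the single-match
convention); higher-order escapes are negligible at small ``mu``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "p_escape",
    "p_escape_any_locus",
    "expected_escapes",
    "max_p_escape",
    "escape_curve",
]


def _log_base(q: float, mu: float, beta: int) -> float:
    # log(q + (1-q)(1-mu)^beta), stable at tiny mu and q
    return float(np.log(q + (1.0 - q) * np.exp(beta * np.log1p(-mu))))


def p_escape(S, q: float, mu: float, beta: int):
    """``1 - (q + (1-q)(1-mu)**beta)**S`` computed in log space.

    ``S`` may be a scalar or array of non-negative host counts.
    """
    if not (0 <= q <= 1 and 0 <= mu <= 1) or beta < 1:
        raise ValueError("require 0<=q<=1, 0<=mu<=1, beta>=1")
    S = np.asarray(S, dtype=float)
    if mu >= 1.0 and q < 1.0:
        out = np.where(S > 0, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out
    out = -np.expm1(S * _log_base(q, mu, beta))
    return float(out) if out.ndim == 0 else out


def p_escape_any_locus(S, q: float, mu: float, beta: int, g: int):
    """Variant counting a mutation at *any* of the ``g`` loci as an escape.

    This is NOT the single-match convention of the closed form above (the
    per-offspring no-escape factor becomes ``(1-mu)**(beta*g)``); exposed
    for sensitivity checks only.
    """
    return p_escape(S, q, 1.0 - (1.0 - mu) ** g, beta)


def expected_escapes(S, q: float, mu: float, beta: int):
    """Expected number of single-match escapes, ``S*(1-q)*beta*mu``
    (escapes are not necessarily unique)."""
    if not (0 <= q <= 1 and 0 <= mu <= 1) or beta < 1:
        raise ValueError("require 0<=q<=1, 0<=mu<=1, beta>=1")
    S = np.asarray(S, dtype=float)
    out = S * (1.0 - q) * beta * mu
    return float(out) if out.ndim == 0 else out


def max_p_escape(q: float, mu: float, beta: int, K: int) -> float:
    """Capacity bound: escape probability at the maximal susceptible biomass
    ``S = K``."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return p_escape(K, q, mu, beta)


def escape_curve(q: float, mu: float, beta: int, K: int, s_max: int,
                 n_points: int = 200) -> pd.DataFrame:
    """Tabulate ``P_S`` and ``E_S`` over ``S in [0, s_max]``."""
    S = np.unique(np.round(np.linspace(0, s_max, n_points)).astype(int))
    return pd.DataFrame({
        "S": S,
        "p_escape": p_escape(S, q, mu, beta),
        "expected_escapes": expected_escapes(S, q, mu, beta),
        "max_p_escape": max_p_escape(q, mu, beta, K),
    })
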