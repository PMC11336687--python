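"""Probability of viral evolutionary emergence from frozen network state.

For a viral match phenotype ``i`` facing susceptible biomass ``S_i`` in a
host population of size ``N`` held constant (the pre-epidemic convention),
the reproductive ratio is

    R0_i = beta * (1 - q) * phi * S_i / (d + phi * N)

-- the expected daughter virions per virion, every adsorption being
absorbing.  Escaping the rank-``j`` single-match biomass ``A_(j)`` adds that
biomass to the numerator, giving the ranked ratios ``R_j_i``.

Two routes to the emergence probability are provided:

* the closed form ``P = sigma + W0(-beta*sigma*e^{-beta*sigma})/beta`` with
  ``sigma = R0/(R0+beta)`` (principal Lambert branch), the root of
  ``P = sigma*(1 - e^{-beta*P})`` -- zero exactly when
  ``R0 <= beta/(beta-1)``;
* a numerical multi-type branching fixed point with the model's exact
  fixed-burst offspring law, including the first-order-in-``mu``
  contribution of single-match escapes, iterated from extinction
  probability 0 (hence converging to the minimal root).

The two differ by the Poisson-vs-fixed-burst convention, an ``O(1/beta)``
gap; the fixed point is the one the lineage-level model obeys exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .core_state import SystemState
from .networks import MatchPhenotype, build_match_phenotypes
from .ssa import RunResult

__all__ = [
    "EmergenceResult",
    "r0",
    "p_star_zeroth",
    "p_star_first_order",
    "emergence_results",
    "expected_p_star",
    "expected_p_star_series",
    "local_maxima",
    "fraction_onsets_preceded",
]


@dataclass
class EmergenceResult:
    phenotype_id: int
    R0: float
    ranked_R: list[float]          # R_1 >= R_2 >= ... (by accessible biomass)
    sigma: float                   # R0/(R0+beta)
    z0: float                      # Lambert argument for R0
    z_ranked: list[float]
    P_star_0: float                # zeroth-order (closed-form) probability
    P_star: float                  # first-order-in-mu fixed point
    weight: float = 0.0


def r0(phenotype: MatchPhenotype, state: SystemState,
       extra_biomass: float = 0.0, *, denominator: str = "total") -> float:
    """Reproductive ratio of a match phenotype against a frozen host state.

    ``denominator="total"`` uses ``d + phi*N`` (every adsorption removes the
    virion); ``"susceptible"`` uses ``d + phi*(S_i + extra)`` instead.
    """
    p = state.params
    N = state.N
    if N <= 0:
        return 0.0
    S = phenotype.S_i + extra_biomass
    if denominator == "total":
        den = p.d + p.phi * N
    elif denominator == "susceptible":
        den = p.d + p.phi * S
    else:
        raise ValueError("denominator must be 'total' or 'susceptible'")
    if den <= 0:
        return 0.0
    return p.beta * (1.0 - p.q) * p.phi * S / den


def _lambert_z(R: float, beta: int) -> float:
    sigma = R / (R + beta)
    return -beta * sigma * np.exp(-beta * sigma)

def p_star_zeroth(R0: float, beta: int) -> float:
    """Closed-form emergence probability (infection-network contribution).

    ``sigma + W0(-beta*sigma*e^{-beta*sigma})/beta``, clipped to [0, 1];
    exactly 0 when ``beta*sigma <= 1`` i.e. ``R0 <= beta/(beta-1)``.
    """
    if R0 < 0:
        raise ValueError("R0 must be non-negative")
    sigma = R0 / (R0 + beta)
    x = beta * sigma
    if x <= 1.0:
        return 0.0
    P = sigma + float(np.real(lambertw(-x * np.exp(-x), k=0))) / beta
    return min(max(P, 0.0), 1.0)


def p_star_first_order(R0: float, ranked_R: Sequence[float], mu: float,
                       beta: int, g: int, *, tol: float = 1e-13,
                       max_iter: int = 500_000,
                       escape_survival: str = "exact") -> float:
    """Emergence probability to first order in ``mu`` via the branching
    fixed point.

    The extinction probability ``eps`` of a focal lineage solves

        eps = (1 - pi) + pi * ((1 - l*m)*eps + m * sum_j eps_j0)**beta

    with per-virion success probability ``pi = R0/beta`` (capped at 1),
    per-offspring single-escape probability ``m = mu*(1-mu)**(g-1)``, and
    escape lineages terminal at zeroth order with extinction probability
    ``eps_j0``.  Iterated from ``eps = 0`` (the map is monotone, so this
    converges to the minimal root); ``P* = 1 - eps``.

    ``escape_survival`` selects how ``eps_j0`` is computed: ``"exact"``
    (default) solves the same fixed-burst fixed point for each escape --
    the convention the model's lineages actually obey, required for
    agreement with direct lineage simulation when the escape term leads
    (subcritical ``R0``); ``"lambert"`` uses the Poisson-burst closed form
    ``1 - p_star_zeroth(R_j, beta)`` instead, which differs by ``O(1/beta)``.
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    pi = R0 / beta
    if pi > 1.0:
        warnings.warn("R0 exceeds beta; success probability capped at 1")
        pi = 1.0
    m = mu * (1.0 - mu) ** (g - 1)
    ell = len(ranked_R)
    if ell * m > 1.0:
        raise ValueError("l*m exceeds 1; mu is not small enough for the "
                         "first-order expansion")
    if escape_survival == "exact":
        esc = m * sum(1.0 - p_star_first_order(Rj, [], 0.0, beta, g,
                                               tol=tol, max_iter=max_iter)
                      for Rj in ranked_R)
    elif escape_survival == "lambert":
        esc = m * sum(1.0 - p_star_zeroth(Rj, beta) for Rj in ranked_R)
    else:
        raise ValueError("escape_survival must be 'exact' or 'lambert'")
    eps = 0.0
    inc = 1.0
    for _ in range(max_iter):
        new = (1.0 - pi) + pi * ((1.0 - ell * m) * eps + esc) ** beta
        inc = abs(new - eps)
        eps = new
        if inc < tol:
            return min(max(1.0 - eps, 0.0), 1.0)
    # near criticality the monotone iteration slows to O(1/n); accept the
    # iterate once increments are far below any statistically relevant scale
    if inc < 1e-9:
        return min(max(1.0 - eps, 0.0), 1.0)
    raise RuntimeError("branching fixed point failed to converge")


def emergence_results(state: SystemState, *, denominator: str = "total",
                      weighting: str = "infection",
                      phenotypes: Optional[list[MatchPhenotype]] = None
                      ) -> list[EmergenceResult]:
    """Per-phenotype emergence quantities for a frozen state.

    Weights ``w_i`` are the probabilities that the next
    susceptible-adsorption event involves phenotype ``i``
    (``w_i ~ V_i * S_i``; ``weighting="abundance"`` uses ``w_i ~ V_i``).
    When every ``V_i*S_i`` is zero the weighting falls back to abundance.
    """
    p = state.params
    if phenotypes is None:
        phenotypes = build_match_phenotypes(state)
    out = []
    for ph in phenotypes:
        R0_i = r0(ph, state, denominator=denominator)
        ranked = [r0(ph, state, extra_biomass=A, denominator=denominator)
                  for A in ph.ranked_biomasses]
        P0 = p_star_zeroth(R0_i, p.beta)
        P1 = p_star_first_order(R0_i, ranked, p.mu, p.beta, p.g)
        out.append(EmergenceResult(
            phenotype_id=ph.phenotype_id, R0=R0_i, ranked_R=ranked,
            sigma=R0_i / (R0_i + p.beta), z0=_lambert_z(R0_i, p.beta),
            z_ranked=[_lambert_z(R, p.beta) for R in ranked],
            P_star_0=P0, P_star=P1))
    if weighting == "infection":
        raw = [ph.V_i * ph.S_i for ph in phenotypes]
        if sum(raw) == 0:
            raw = [ph.V_i for ph in phenotypes]
    elif weighting == "abundance":
        raw = [ph.V_i for ph in phenotypes]
    else:
        raise ValueError("weighting must be 'infection' or 'abundance'")
    tot = sum(raw)
    for res, w in zip(out, raw):
        res.weight = w / tot if tot > 0 else 0.0
    return out


def expected_p_star(state: SystemState, *, n_ranks: int = 3, **kwargs
                    ) -> tuple[float, float, list[float]]:
    """Population expectations ``(<P*>, <R0>, [<R_k - R0>, k=1..n_ranks])``.

    Missing ranks contribute a zero differential.  Raises when no virion is
    extant (there is nothing to sample).
    """
    if state.V <= 0:
        raise ValueError("expected_p_star requires at least one extant virion")
    results = emergence_results(state, **kwargs)
    EP = sum(r.weight * r.P_star for r in results)
    ER0 = sum(r.weight * r.R0 for r in results)
    diffs = []
    for k in range(n_ranks):
        diffs.append(sum(
            r.weight * ((r.ranked_R[k] - r.R0) if k < len(r.ranked_R) else 0.0)
            for r in results))
    return EP, ER0, diffs


def expected_p_star_series(result: RunResult, *, n_ranks: int = 3, **kwargs
                           ) -> pd.DataFrame:
    """Time-resolved expectations, one row per recorded sample.

    Columns ``time, EPstar, ER0, ED1..EDn``; NaN where the viral population
    is extinct.
    """
    rows = []
    nan_row = [float("nan")] * (2 + n_ranks)
    for i, t in enumerate(result.series.times):
        if result.series.V[i] == 0:
            rows.append([t] + nan_row)
            continue
        EP, ER0, diffs = expected_p_star(result.state_at(i),
                                         n_ranks=n_ranks, **kwargs)
        rows.append([t, EP, ER0] + diffs)
    cols = ["time", "EPstar", "ER0"] + [f"ED{k+1}" for k in range(n_ranks)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Outbreak / early-warning descriptive helpers
# ---------------------------------------------------------------------------

def local_maxima(values: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Indices of strict-or-plateau local maxima above ``floor``.

    A plateau reports its first index.  NaNs never qualify.
    """
    v = np.asarray(values, dtype=float)
    idx = []
    n = len(v)
    for i in range(n):
        if not np.isfinite(v[i]) or v[i] <= floor:
            continue
        left = v[i - 1] if i > 0 else -np.inf
        jr = i + 1
        while jr < n and v[jr] == v[i]:
            jr += 1
        right = v[jr] if jr < n else -np.inf
        if v[i] > left and v[i] > right:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def fraction_onsets_preceded(times: np.ndarray, V: np.ndarray,
                             epstar: np.ndarray, *, v_floor: float,
                             window: float) -> tuple[int, int]:
    """Count outbreak onsets preceded by a local maximum of ``<P*>``.

    An outbreak onset is a local maximum of total viral abundance above
    ``v_floor``; it counts as "preceded" when some local maximum of
    ``epstar`` falls within ``[t_peak - window, t_peak]``.  Returns
    ``(n_preceded, n_outbreaks)``.
    """
    times = np.asarray(times, dtype=float)
    peaks = local_maxima(np.asarray(V, dtype=float), floor=v_floor)
    ep_peaks = times[local_maxima(np.asarray(epstar, dtype=float))]
    n_ok = 0
    for i in peaks:
        tp = times[i]
        if np.any((ep_peaks >= tp - window) & (ep_peaks <= tp)):
            n_ok += 1
    return n_ok, len(peaks)
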