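"""Diversity indices, single-match diversity Dp, and phylogeny summaries.

"Shannon diversity" is rendered throughout in the Hill (effective-number)
convention, ``exp(-sum p ln p)``: 1 for a monomorphic population, equal to
the richness for a uniform one.  The raw entropy is available via
:func:`shannon_entropy`.  The single-match diversity ``Dp`` applies the same
form to the spacer-layer biomass frequencies ``N_sigma/N_tri`` of the
tripartite escape network; it tracks how many escape pathways effectively
protect the host biomass, and its within-control-phase decline is the
signature of increasingly fragile host control.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .core_state import SystemState
from .networks import TripartiteNetwork, build_tripartite
from .ssa import RunResult

__all__ = [
    "shannon_entropy",
    "hill_shannon",
    "dp",
    "dp_per_virus",
    "phylo_summaries",
    "to_newick",
]


def shannon_entropy(abundances: Iterable[float]) -> float:
    """``-sum p ln p`` over normalized frequencies; zero terms contribute 0."""
    a = np.asarray(list(abundances), dtype=float)
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("entropy requires at least one positive abundance")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    p = a / a.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def hill_shannon(abundances: Iterable[float]) -> float:
    """Effective number of strains, ``exp(-sum p ln p)``."""
    return math.exp(shannon_entropy(abundances))


def dp(obj: Union[SystemState, TripartiteNetwork], **kwargs) -> float:
    """Single-match diversity of the tripartite escape network.

    ``Dp = exp(-sum_sigma f_sigma ln f_sigma)`` with
    ``f_sigma = N_sigma / N_tri``.  Returns NaN when no spacer confers a
    single match (the diversity of an empty set is undefined).
    """
    net = obj if isinstance(obj, TripartiteNetwork) else \
        build_tripartite(obj, **kwargs)
    if not net.spacer_biomass or net.N_tri <= 0:
        return float("nan")
    return hill_shannon(net.spacer_biomass.values())


def dp_per_virus(state: SystemState) -> dict[int, float]:
    """Dp restricted to each viral strain's own single matches.

    For viral strain ``v`` the spacer layer is the set of alleles that
    singly protect some host from ``v``; NaN where the strain has none.
    """
    out: dict[int, float] = {}
    for v in state.viruses:
        biomass: dict[int, int] = {}
        for h in state.hosts:
            m = h.spacers & v.alleles
            if len(m) == 1:
                (sigma,) = m
                biomass[sigma] = biomass.get(sigma, 0) + h.abundance
        out[v.id] = hill_shannon(biomass.values()) if biomass else float("nan")
    return out


def phylo_summaries(result: RunResult) -> pd.DataFrame:
    """Per-sample diversity trace from one run.

    Columns: ``time, host_hill, host_entropy, host_richness, viral_richness,
    mean_spacer_len, mean_creation_time, dp`` -- means are abundance-weighted
    over extant host strains.  Raises on orphan parent references.
    """
    for rec in list(result.hosts.values()) + list(result.viruses.values()):
        if rec.parent_id is not None and rec.parent_id not in result.hosts \
                and rec.parent_id not in result.viruses:
            raise ValueError(f"orphan parent reference: {rec.parent_id}")
    s = result.series
    rows = []
    for i, t in enumerate(s.times):
        hs = s.host_samples[i]
        if hs:
            ab = np.array(list(hs.values()), dtype=float)
            ids = list(hs.keys())
            hill = hill_shannon(ab)
            ent = shannon_entropy(ab)
            lens = np.array([len(result.hosts[j].spacers) for j in ids])
            births = np.array([result.hosts[j].t_birth for j in ids])
            wts = ab / ab.sum()
            mean_len = float((wts * lens).sum())
            mean_birth = float((wts * births).sum())
        else:
            hill = ent = mean_len = mean_birth = float("nan")
        rows.append((t, hill, ent, len(hs), len(s.viral_samples[i]),
                     mean_len, mean_birth, dp(result.state_at(i))))
    return pd.DataFrame(rows, columns=[
        "time", "host_hill", "host_entropy", "host_richness",
        "viral_richness", "mean_spacer_len", "mean_creation_time", "dp"])


def to_newick(strains: dict, kind: Optional[str] = None) -> str:
    """Forward phylogeny as a Newick string.

    Each strain is a named node; branch length is ``child.t_birth -
    parent.t_birth``.  Multiple founders are joined under an artificial
    root of zero height.
    """
    children: dict[Optional[int], list[int]] = {}
    for sid, rec in sorted(strains.items()):
        parent = rec.parent_id if rec.parent_id in strains else None
        children.setdefault(parent, []).append(sid)

    def render(sid: int) -> str:
        rec = strains[sid]
        parent_t = strains[rec.parent_id].t_birth \
            if rec.parent_id in strains else 0.0
        bl = rec.t_birth - parent_t
        kids = children.get(sid, [])
        if kids:
            return "(" + ",".join(render(c) for c in kids) + f"){sid}:{bl:g}"
        return f"{sid}:{bl:g}"

    roots = children.get(None, [])
    if not roots:
        return ";"
    if len(roots) == 1:
        return render(roots[0]) + ";"
    return "(" + ",".join(render(r) for r in roots) + ")root:0;"
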