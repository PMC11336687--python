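"""Replicate orchestration, parameter sweeps, combined analytics, fixtures.

Sweeps are laid out on non-dimensional axes: *ecological* grids vary burst
size ``beta`` and the maximal adsorption ratio ``phi*K/d`` (the number of
host cells at capacity adsorbable within one virion lifetime), realized by
fixing the anchors ``phi``, ``d``, ``r`` and solving ``K`` from the ratio;
*evolutionary* grids vary the spacer-acquisition probability ``q`` and the
protospacer mutation probability ``mu``.  Every replicate's seed is a
deterministic function of (base seed, cell, replicate), so cells can be run
in any order and reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core_state import HostStrain, Params, SystemState, ViralStrain
from .diversity import dp as _dp
from .diversity import hill_shannon
from .emergence import emergence_results
from .networks import build_tripartite
from .shc import DetectorConfig, summarize_run
from .ssa import RunResult, run

__all__ = [
    "SweepSpec",
    "run_sweep",
    "analyze_run",
    "make_fixture",
    "reduced_params",
    "cell_seed",
    "load_config",
    "params_to_dict",
    "write_manifest",
]


def reduced_params(seed: int = 0, **overrides) -> Params:
    """Reduced-scale study conditions exhibiting alternating dynamics.

    K=2000, beta=50, q=1e-3, mu=5e-5, r=1, d=0.1, with ``phi`` set so the
    naive-host reproductive ratio ``beta*phi*K/(d+phi*K)`` equals 5 (an
    epidemic-capable virus), t_max=500.  Relative to full scale (K ~ 1e5,
    q=1e-5, mu=5e-7) the evolutionary probabilities are raised ~100x so the
    expected numbers of spacer acquisitions and escape mutations per
    epidemic stay of order one-to-a-few despite the ~50x smaller
    populations -- the same drift-countering adjustment the full-scale
    conditions themselves apply to their predecessors' rates.
    """
    K = overrides.pop("K", 2000)
    d = overrides.pop("d", 0.1)
    base = dict(r=1.0, d=d, phi=d / (9.0 * K), q=1e-3, mu=5e-5, beta=50,
                g=15, K=K, w=0.0, t_max=500.0, sample_dt=1.0, seed=seed)
    base.update(overrides)
    return Params(**base)


def cell_seed(base_seed: int, cell_index: int, rep: int) -> int:
    """Deterministic per-replicate seed (independent of execution order)."""
    return (base_seed + 100_003 * cell_index + 7919 * rep) % 2**31


@dataclass
class SweepSpec:
    """A replicate grid over non-dimensional parameter axes."""

    kind: str                         # "ecological" | "evolutionary"
    axis1: list = field(default_factory=list)  # beta values | q values
    axis2: list = field(default_factory=list)  # phi*K/d values | mu values
    replicates: int = 20
    base: Params = field(default_factory=Params)
    base_seed: int = 0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    max_events: int = 2_000_000_000

    def cells(self) -> list[tuple[dict, Params]]:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        out = []
        for a in self.axis1:
            for b in self.axis2:
                if self.kind == "ecological":
                    K = int(round(b * self.base.d / self.base.phi))
                    if K < 1:
                        raise ValueError(
                            f"adsorption ratio {b} yields K={K} < 1")
                    p = replace(self.base, beta=int(a), K=K)
                    label = {"beta": int(a), "adsorption_ratio": b, "K": K}
                else:
                    p = replace(self.base, q=float(a), mu=float(b))
                    label = {"q": float(a), "mu": float(b)}
                out.append((label, p))
        return out


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Execute the grid; one summary row per cell.

    Per-replicate failures are logged in the ``n_failed`` column rather than
    aborting the sweep.
    """
    rows = []
    for ci, (label, base_p) in enumerate(spec.cells()):
        n_shc, durations, alt, vext, hext, tvs, ths = [], [], [], [], [], [], []
        n_failed = 0
        for rep in range(spec.replicates):
            p = replace(base_p, seed=cell_seed(spec.base_seed, ci, rep))
            try:
                res = run(p, max_events=spec.max_events)
            except Exception:
                n_failed += 1
                continue
            summ = summarize_run(res, spec.detector)
            n_shc.append(summ.n_shc)
            durations.extend(summ.durations)
            alt.append(summ.alternating)
            vext.append(summ.t_virus_extinct is not None)
            hext.append(summ.t_host_extinct is not None)
            if summ.t_virus_extinct is not None:
                tvs.append(summ.t_virus_extinct)
            if summ.t_host_extinct is not None:
                ths.append(summ.t_host_extinct)
        row = dict(label)
        n_ok = spec.replicates - n_failed
        row.update({
            "n_replicates": n_ok,
            "n_failed": n_failed,
            "mean_n_shc": float(np.mean(n_shc)) if n_shc else float("nan"),
            "sd_n_shc": float(np.std(n_shc)) if n_shc else float("nan"),
            "max_n_shc": int(np.max(n_shc)) if n_shc else 0,
            "mean_shc_duration": float(np.mean(durations)) if durations
            else float("nan"),
            "frac_alternating": float(np.mean(alt)) if alt else float("nan"),
            "frac_virus_extinct": float(np.mean(vext)) if vext else float("nan"),
            "frac_host_extinct": float(np.mean(hext)) if hext else float("nan"),
            "mean_t_virus_extinct": float(np.mean(tvs)) if tvs else float("nan"),
            "mean_t_host_extinct": float(np.mean(ths)) if ths else float("nan"),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_run(result: RunResult, *, n_ranks: int = 3,
                **emergence_kwargs) -> pd.DataFrame:
    """Per-sample combined analytics for one run.

    Builds each sample's phenotypes once and derives host Hill--Shannon
    diversity, richness, mean spacer-array length, abundance-weighted mean
    strain creation time, the single-match diversity ``Dp``, and the
    emergence expectations ``<P*>, <R0>, <R_k - R0>``.
    """
    s = result.series
    rows = []
    for i, t in enumerate(s.times):
        hs = s.host_samples[i]
        state = result.state_at(i)
        if hs:
            ab = np.array(list(hs.values()), dtype=float)
            ids = list(hs.keys())
            wts = ab / ab.sum()
            hill = hill_shannon(ab)
            mean_len = float((wts * np.array(
                [len(result.hosts[j].spacers) for j in ids])).sum())
            mean_birth = float((wts * np.array(
                [result.hosts[j].t_birth for j in ids])).sum())
        else:
            hill = mean_len = mean_birth = float("nan")
        net = build_tripartite(state)
        dpv = _dp(net)
        if s.V[i] > 0:
            res = emergence_results(state, phenotypes=net.phenotypes,
                                    **emergence_kwargs)
            EP = sum(r.weight * r.P_star for r in res)
            ER0 = sum(r.weight * r.R0 for r in res)
            diffs = [sum(r.weight * ((r.ranked_R[k] - r.R0)
                                     if k < len(r.ranked_R) else 0.0)
                         for r in res) for k in range(n_ranks)]
        else:
            EP = ER0 = float("nan")
            diffs = [float("nan")] * n_ranks
        rows.append([t, int(s.N[i]), int(s.V[i]), hill, len(hs),
                     len(s.viral_samples[i]), mean_len, mean_birth, dpv,
                     EP, ER0] + diffs)
    cols = ["time", "N", "V", "host_hill", "host_richness", "viral_richness",
            "mean_spacer_len", "mean_creation_time", "dp", "EPstar", "ER0"] \
        + [f"ED{k+1}" for k in range(n_ranks)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, *, seed: int = 0, g: int = 3):
    """Deterministic toy objects used across tests and examples.

    ``toy_network``: hosts {a}x200, {b}x100, {a,b}x50 against virus (a,b,x).
    ``toy_state``: a small random canonical state drawn from ``seed``.
    ``square_wave_trace``: (times, N, K) with N=K on [0,300] and [500,900],
    0.2K elsewhere.
    """
    if kind == "toy_network":
        a, b, x = 1, 2, 3
        params = Params(g=3)
        hosts = [HostStrain(1, frozenset({a}), 200),
                 HostStrain(2, frozenset({b}), 100),
                 HostStrain(3, frozenset({a, b}), 50)]
        viruses = [ViralStrain(4, (a, b, x), 10)]
        return SystemState(0.0, hosts, viruses, params)
    if kind == "toy_state":
        rng = np.random.default_rng(seed)
        params = Params(g=g)
        pool = list(range(1, 2 * g + 1))
        hosts, viruses = [], []
        sid = 1
        genos = set()
        for _ in range(int(rng.integers(1, 6))):
            geno = frozenset(rng.choice(pool, size=rng.integers(0, g + 1),
                                        replace=False).tolist())
            if geno in genos:
                continue
            genos.add(geno)
            hosts.append(HostStrain(sid, geno, int(rng.integers(1, 300))))
            sid += 1
        reps = set()
        for _ in range(int(rng.integers(1, 6))):
            rep = tuple(int(x) for x in rng.choice(pool, size=g, replace=True))
            if rep in reps:
                continue
            reps.add(rep)
            viruses.append(ViralStrain(sid, rep, int(rng.integers(1, 100))))
            sid += 1
        return SystemState(0.0, hosts, viruses, params)
    if kind == "square_wave_trace":
        K = 1000.0
        times = np.arange(0.0, 1000.0 + 1e-9)
        N = np.where(((times >= 0) & (times <= 300))
                     | ((times >= 500) & (times <= 900)), K, 0.2 * K)
        return times, N, K
    raise ValueError(f"unknown fixture kind: {kind!r}")


# ---------------------------------------------------------------------------
# Config / manifest
# ---------------------------------------------------------------------------

def params_to_dict(p: Params) -> dict:
    return dataclasses.asdict(p)


def load_config(path) -> Params:
    """Read a YAML mapping of Params fields (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(Params)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Params(**raw)


def write_manifest(path, params: Params, *, seeds: list[int],
                   extra: Optional[dict] = None) -> None:
    """Record config hash, seeds and package version for a run or sweep."""
    from . import __version__
    cfg = params_to_dict(params)
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "package": "altdyn",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": list(seeds),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
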