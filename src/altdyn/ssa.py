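"""Exact event-driven simulation of CRISPR-mediated host--virus coevolution.

Implements Gillespie's direct method over a dynamic strain space.  Event
channels, per host strain ``k`` (abundance ``H_k``) and viral strain ``j``
(abundance ``V_j``), with ``N`` the total host biomass:

* host replication at rate ``r*H_k`` (clonal; daughters inherit the strain),
* density-dependent competition death at rate ``r*(N/K)*H_k``,
* optional washout at rate ``w*H_k``,
* viral decay at rate ``d*V_j``,
* adsorption at rate ``phi*V_j*H_k``.

Adsorption is absorbing for the virion.  A protected host (at least one
spacer matching a protospacer) destroys the virion.  An unprotected host
evades lysis with probability ``q``, integrating one protospacer (a
uniformly chosen locus) as a new spacer; otherwise it is lysed, releasing
``beta`` virions, each locus of each offspring mutating independently with
probability ``mu`` to a fresh allele (infinite alleles).

For exactness at low cost, adsorption is drawn as one aggregate channel of
rate ``phi*V_tot*N_tot`` followed by proportional sampling of the (virus,
host) pair, and burst mutations are drawn as a single
``Binomial(beta*g, mu)`` count whose mutated locus-slots are then placed
uniformly -- both distributionally identical to the naive per-pair /
per-Bernoulli construction.

The inner loop is compiled with numba when available (a pure-Python fallback
runs the identical code path).  Only strain-creating events (spacer
acquisition, mutant bursts) and sampling boundaries leave the compiled loop.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_state import (
    AlleleRegistry,
    HostStrain,
    Params,
    SystemState,
    ViralStrain,
    canonicalize,
)

__all__ = [
    "EventChannel",
    "TimeSeries",
    "RunResult",
    "channel_rates",
    "apply_adsorption",
    "default_initial_state",
    "run",
    "write_timeseries",
    "write_totals",
    "write_phylogeny",
]


# ---------------------------------------------------------------------------
# Inner kernel (numba-compatible; jitted below when numba is present)
# ---------------------------------------------------------------------------

def _seed_kernel(seed):
    np.random.seed(seed)


def _pick(arr, tot):
    # proportional sampling by linear cumulative scan
    u = np.random.random() * tot
    c = 0.0
    n = arr.shape[0]
    for i in range(n):
        c += arr[i]
        if u < c:
            return i
    for i in range(n - 1, -1, -1):
        if arr[i] > 0:
            return i
    return 0


def _advance(t, t_stop, H, Vab, prot, ext_h, ext_v, tot_ext,
             r, d, phi, K, w, q, mu, beta, g, events, max_events):
    """Advance until t_stop, or until an event that changes the strain space.

    Returns (t, code, j, k, M, events) with codes:
      0 reached t_stop; 1 spacer acquisition (virus j, host k);
      2 lysis with M mutated locus-slots (virus j, host k);
      4 event guard exceeded; 5 non-finite total rate.
    Plain lyses, protected adsorptions, demographic and decay events are
    applied in place.  ext_h/ext_v record exact per-strain extinction times;
    tot_ext[0]/tot_ext[1] the first time V/N hits zero (-1 while unset).
    """
    N = 0
    for i in range(H.shape[0]):
        N += H[i]
    Vt = 0
    for i in range(Vab.shape[0]):
        Vt += Vab[i]
    beta_g = beta * g
    while True:
        fN = float(N)
        fV = float(Vt)
        r_rep = r * fN
        r_death = (r * fN / K + w) * fN
        r_dec = d * fV
        r_ads = phi * fV * fN
        total = r_rep + r_death + r_dec + r_ads
        if not total < 1e308:
            return t, 5, -1, -1, 0, events
        if total <= 0.0:
            return t_stop, 0, -1, -1, 0, events
        dt = -np.log(np.random.random()) / total
        if t + dt >= t_stop:
            return t_stop, 0, -1, -1, 0, events
        t = t + dt
        events += 1
        if events >= max_events:
            return t, 4, -1, -1, 0, events
        u = np.random.random() * total
        if u < r_rep:
            k = _pick(H, fN)
            H[k] += 1
            N += 1
        elif u < r_rep + r_death:
            k = _pick(H, fN)
            H[k] -= 1
            N -= 1
            if H[k] == 0:
                ext_h[k] = t
            if N == 0 and tot_ext[1] < 0:
                tot_ext[1] = t
        elif u < r_rep + r_death + r_dec:
            j = _pick(Vab, fV)
            Vab[j] -= 1
            Vt -= 1
            if Vab[j] == 0:
                ext_v[j] = t
            if Vt == 0 and tot_ext[0] < 0:
                tot_ext[0] = t
        else:
            j = _pick(Vab, fV)
            k = _pick(H, fN)
            # adsorption always removes the virion
            Vab[j] -= 1
            Vt -= 1
            if Vab[j] == 0:
                ext_v[j] = t
            if Vt == 0 and tot_ext[0] < 0:
                tot_ext[0] = t
            if prot[j, k] == 1:
                continue
            if np.random.random() < q:
                return t, 1, j, k, 0, events
            # lysis
            H[k] -= 1
            N -= 1
            if H[k] == 0:
                ext_h[k] = t
            if N == 0 and tot_ext[1] < 0:
                tot_ext[1] = t
            M = np.random.binomial(beta_g, mu)
            if M == 0:
                Vab[j] += beta
                Vt += beta
                if Vab[j] == beta:
                    ext_v[j] = -1.0
                if tot_ext[0] == t:
                    tot_ext[0] = -1.0
            else:
                return t, 2, j, k, M, events


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _pick = njit(cache=True, inline="always")(_pick)
    _advance = njit(cache=True)(_advance)
    _seed_kernel = njit(cache=True)(_seed_kernel)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# Channel inspection / single-event application (reference semantics)
# ---------------------------------------------------------------------------

@dataclass
class EventChannel:
    kind: str
    actors: tuple
    rate: float


def channel_rates(state: SystemState) -> list[EventChannel]:
    """Enumerate every event channel of a canonical state with its rate."""
    p = state.params
    N = state.N
    out: list[EventChannel] = []
    for h in state.hosts:
        out.append(EventChannel("host_replication", (h.id,), p.r * h.abundance))
        out.append(EventChannel("host_competition_death", (h.id,),
                                p.r * (N / p.K) * h.abundance))
        if p.w > 0:
            out.append(EventChannel("host_washout", (h.id,), p.w * h.abundance))
    for v in state.viruses:
        out.append(EventChannel("viral_decay", (v.id,), p.d * v.abundance))
        for h in state.hosts:
            out.append(EventChannel("adsorption", (v.id, h.id),
                                    p.phi * v.abundance * h.abundance))
    return out


def apply_adsorption(state: SystemState, virus: ViralStrain, host: HostStrain,
                     rng: np.random.Generator,
                     registry: Optional[AlleleRegistry] = None) -> SystemState:
    """Apply one adsorption event to a copy of ``state`` (reference path).

    Mirrors the kernel semantics exactly; used for event-level tests and as
    executable documentation of the reaction.  The engine's compiled loop is
    the production path.
    """
    if virus.abundance < 1 or host.abundance < 1:
        raise ValueError("adsorption requires at least one virion and one host cell")
    p = state.params
    if registry is None:
        top = 0
        for h in state.hosts:
            top = max(top, max(h.spacers, default=0))
        for v in state.viruses:
            top = max(top, max(v.repertoire, default=0))
        registry = AlleleRegistry(top + 1)
    hosts = [replace(h) for h in state.hosts]
    viruses = [replace(v) for v in state.viruses]
    vmap = {v.id: v for v in viruses}
    hmap = {h.id: h for h in hosts}
    v = vmap[virus.id]
    h = hmap[host.id]
    v.abundance -= 1  # absorbing
    if not h.spacers.isdisjoint(v.alleles):
        pass  # protected: virion destroyed, nothing else
    elif rng.random() < p.q:
        s = v.repertoire[rng.integers(p.g)]
        if s not in h.spacers:
            h.abundance -= 1
            geno = h.spacers | {s}
            for other in hosts:
                if other.spacers == geno:
                    other.abundance += 1
                    break
            else:
                nid = max(list(hmap) + list(vmap)) + 1
                hosts.append(HostStrain(nid, geno, 1, parent_id=h.id,
                                        t_birth=state.t))
    else:
        h.abundance -= 1
        n_mut = rng.binomial(p.beta * p.g, p.mu)
        slots = rng.choice(p.beta * p.g, size=n_mut, replace=False) if n_mut else []
        per_off: dict[int, list[int]] = {}
        for s in sorted(int(x) for x in slots):
            per_off.setdefault(s // p.g, []).append(s % p.g)
        v.abundance += p.beta - len(per_off)
        nid = max(list(hmap) + list(vmap)) + 1
        for _, loci in sorted(per_off.items()):
            rep = list(v.repertoire)
            for loc in loci:
                rep[loc] = registry.issue()
            viruses.append(ViralStrain(nid, tuple(rep), 1, parent_id=v.id,
                                       t_birth=state.t))
            nid += 1
    return SystemState(state.t, hosts, viruses, state.params)


# ---------------------------------------------------------------------------
# Run results
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    times: np.ndarray
    N: np.ndarray
    V: np.ndarray
    host_richness: np.ndarray
    viral_richness: np.ndarray
    host_samples: list  # list[dict[strain_id, abundance]]
    viral_samples: list


@dataclass
class RunResult:
    params: Params
    series: TimeSeries
    hosts: dict[int, HostStrain]     # every strain ever created
    viruses: dict[int, ViralStrain]
    t_virus_extinct: Optional[float]
    t_host_extinct: Optional[float]
    n_events: int

    def state_at(self, i: int) -> SystemState:
        """Frozen SystemState at sample index ``i`` (canonical by construction)."""
        hs = [replace(self.hosts[sid], abundance=a)
              for sid, a in self.series.host_samples[i].items()]
        vs = [replace(self.viruses[sid], abundance=a)
              for sid, a in self.series.viral_samples[i].items()]
        return SystemState(float(self.series.times[i]), hs, vs, self.params)

    @property
    def final_state(self) -> SystemState:
        return self.state_at(len(self.series.times) - 1)


def default_initial_state(params: Params,
                          registry: Optional[AlleleRegistry] = None) -> SystemState:
    """100 naive hosts and 100 identical virions (one fresh repertoire)."""
    if registry is None:
        registry = AlleleRegistry()
    rep = tuple(registry.issue_many(params.g))
    hosts = [HostStrain(1, frozenset(), 100, None, 0.0)]
    viruses = [ViralStrain(2, rep, 100, None, 0.0)]
    return SystemState(0.0, hosts, viruses, params)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    def __init__(self, params: Params, initial: SystemState,
                 max_events: int, max_wall_s: Optional[float]):
        self.p = params
        self.max_events = max_events
        self.max_wall_s = max_wall_s
        initial = canonicalize(initial)
        _seed_kernel(int(params.seed) % 2**31)
        self.rng = np.random.default_rng([int(params.seed) % 2**31, 0x5EED])

        top_allele = 0
        top_id = 0
        for h in initial.hosts:
            top_allele = max(top_allele, max(h.spacers, default=0))
            top_id = max(top_id, h.id)
        for v in initial.viruses:
            top_allele = max(top_allele, max(v.repertoire, default=0))
            top_id = max(top_id, v.id)
        self.registry = AlleleRegistry(top_allele + 1)
        self.next_strain_id = top_id + 1

        self.host_rec: dict[int, HostStrain] = {}
        self.vir_rec: dict[int, ViralStrain] = {}
        self.h_ids: list[int] = []
        self.h_geno: list[frozenset] = []
        self.v_ids: list[int] = []
        self.v_rep: list[tuple] = []
        self.h_index: dict[frozenset, int] = {}
        self.v_index: dict[tuple, int] = {}
        H = []
        for h in initial.hosts:
            self.host_rec[h.id] = replace(h)
            self.h_index[h.spacers] = len(self.h_ids)
            self.h_ids.append(h.id)
            self.h_geno.append(h.spacers)
            H.append(h.abundance)
        V = []
        for v in initial.viruses:
            self.vir_rec[v.id] = replace(v)
            self.v_index[v.repertoire] = len(self.v_ids)
            self.v_ids.append(v.id)
            self.v_rep.append(v.repertoire)
            V.append(v.abundance)
        self.H = np.asarray(H, dtype=np.int64)
        self.Vab = np.asarray(V, dtype=np.int64)
        self.ext_h = np.full(len(self.h_ids), -1.0)
        self.ext_v = np.full(len(self.v_ids), -1.0)
        self.tot_ext = np.array([-1.0, -1.0])
        if self.Vab.sum() == 0:
            self.tot_ext[0] = initial.t
        if self.H.sum() == 0:
            self.tot_ext[1] = initial.t
        self.prot = self._build_prot()
        self.events = 0

        self.times: list[float] = []
        self.sN: list[int] = []
        self.sV: list[int] = []
        self.h_samples: list[dict] = []
        self.v_samples: list[dict] = []

    # -- protection matrix -------------------------------------------------
    def _build_prot(self) -> np.ndarray:
        prot = np.zeros((len(self.v_ids), len(self.h_ids)), dtype=np.uint8)
        v_alleles = [frozenset(rep) for rep in self.v_rep]
        for j, al in enumerate(v_alleles):
            for k, sp in enumerate(self.h_geno):
                if not sp.isdisjoint(al):
                    prot[j, k] = 1
        return prot

    def _append_host(self, geno: frozenset, strain_id: int) -> int:
        pos = len(self.h_ids)
        self.h_ids.append(strain_id)
        self.h_geno.append(geno)
        self.h_index[geno] = pos
        self.H = np.append(self.H, np.int64(0))
        self.ext_h = np.append(self.ext_h, -1.0)
        col = np.zeros((self.prot.shape[0], 1), dtype=np.uint8)
        for j, rep in enumerate(self.v_rep):
            if not geno.isdisjoint(rep):
                col[j, 0] = 1
        self.prot = np.hstack([self.prot, col])
        return pos

    def _append_virus(self, rep: tuple, strain_id: int) -> int:
        pos = len(self.v_ids)
        self.v_ids.append(strain_id)
        self.v_rep.append(rep)
        self.v_index[rep] = pos
        self.Vab = np.append(self.Vab, np.int64(0))
        self.ext_v = np.append(self.ext_v, -1.0)
        al = frozenset(rep)
        row = np.zeros((1, self.prot.shape[1]), dtype=np.uint8)
        for k, sp in enumerate(self.h_geno):
            if not sp.isdisjoint(al):
                row[0, k] = 1
        self.prot = np.vstack([self.prot, row])
        return pos

    # -- event handlers (strain-space changes) ------------------------------
    def _acquisition(self, j: int, k: int, t: float) -> None:
        p = self.p
        locus = int(self.rng.integers(p.g))
        s = self.v_rep[j][locus]
        geno = self.h_geno[k]
        if s in geno:
            return  # re-acquisition is a no-op; the cell stays put
        self.H[k] -= 1
        if self.H[k] == 0:
            self.ext_h[k] = t
        new_geno = geno | {s}
        pos = self.h_index.get(new_geno)
        if pos is None:
            sid = self.next_strain_id
            self.next_strain_id += 1
            self.host_rec[sid] = HostStrain(sid, new_geno, 0,
                                            parent_id=self.h_ids[k], t_birth=t)
            pos = self._append_host(new_geno, sid)
        self.H[pos] += 1
        if self.ext_h[pos] >= 0:
            self.ext_h[pos] = -1.0
            self.host_rec[self.h_ids[pos]].t_extinct = None

    def _mutant_burst(self, j: int, k: int, M: int, t: float) -> None:
        p = self.p
        slots = self.rng.choice(p.beta * p.g, size=M, replace=False)
        per_off: dict[int, list[int]] = {}
        for s in sorted(int(x) for x in slots):
            per_off.setdefault(s // p.g, []).append(s % p.g)
        wild = p.beta - len(per_off)
        if wild > 0:
            if self.Vab[j] == 0:
                self.ext_v[j] = -1.0
                self.vir_rec[self.v_ids[j]].t_extinct = None
            self.Vab[j] += wild
            if self.tot_ext[0] == t:
                self.tot_ext[0] = -1.0
        parent_rep = self.v_rep[j]
        parent_id = self.v_ids[j]
        for _, loci in sorted(per_off.items()):
            rep = list(parent_rep)
            for loc in loci:
                rep[loc] = self.registry.issue()
            rep = tuple(rep)
            sid = self.next_strain_id
            self.next_strain_id += 1
            self.vir_rec[sid] = ViralStrain(sid, rep, 0, parent_id=parent_id,
                                            t_birth=t)
            pos = self._append_virus(rep, sid)
            self.Vab[pos] += 1
            if self.tot_ext[0] == t:
                self.tot_ext[0] = -1.0

    # -- sampling / compaction ----------------------------------------------
    def _record(self, t: float) -> None:
        hs = {self.h_ids[i]: int(a) for i, a in enumerate(self.H) if a > 0}
        vs = {self.v_ids[i]: int(a) for i, a in enumerate(self.Vab) if a > 0}
        self.times.append(t)
        self.sN.append(int(self.H.sum()))
        self.sV.append(int(self.Vab.sum()))
        self.h_samples.append(hs)
        self.v_samples.append(vs)

    def _compact(self) -> None:
        keep_h = [i for i, a in enumerate(self.H) if a > 0]
        keep_v = [i for i, a in enumerate(self.Vab) if a > 0]
        if len(keep_h) == len(self.h_ids) and len(keep_v) == len(self.v_ids):
            return
        for i, sid in enumerate(self.h_ids):
            if self.H[i] == 0:
                rec = self.host_rec[sid]
                rec.abundance = 0
                rec.t_extinct = self.ext_h[i] if self.ext_h[i] >= 0 else rec.t_extinct
        for i, sid in enumerate(self.v_ids):
            if self.Vab[i] == 0:
                rec = self.vir_rec[sid]
                rec.abundance = 0
                rec.t_extinct = self.ext_v[i] if self.ext_v[i] >= 0 else rec.t_extinct
        self.h_ids = [self.h_ids[i] for i in keep_h]
        self.h_geno = [self.h_geno[i] for i in keep_h]
        self.v_ids = [self.v_ids[i] for i in keep_v]
        self.v_rep = [self.v_rep[i] for i in keep_v]
        self.h_index = {g: i for i, g in enumerate(self.h_geno)}
        self.v_index = {r: i for i, r in enumerate(self.v_rep)}
        self.H = self.H[keep_h]
        self.Vab = self.Vab[keep_v]
        self.ext_h = self.ext_h[keep_h]
        self.ext_v = self.ext_v[keep_v]
        if len(keep_v) and len(keep_h):
            self.prot = self.prot[np.ix_(keep_v, keep_h)]
        else:
            self.prot = np.zeros((len(keep_v), len(keep_h)), dtype=np.uint8)

    # -- main loop -----------------------------------------------------------
    def run(self) -> RunResult:
        p = self.p
        t = 0.0
        t0_wall = _time.monotonic()
        self._record(t)
        sample_idx = 1
        while t < p.t_max:
            next_s = min(sample_idx * p.sample_dt, p.t_max)
            t, code, j, k, M, self.events = _advance(
                t, next_s, self.H, self.Vab, self.prot, self.ext_h, self.ext_v,
                self.tot_ext, p.r, p.d, p.phi, float(p.K), p.w, p.q, p.mu,
                p.beta, p.g, self.events, self.max_events)
            if code == 0:
                self._record(t)
                self._compact()
                if t >= p.t_max:
                    break
                sample_idx += 1
                if self.max_wall_s is not None and \
                        _time.monotonic() - t0_wall > self.max_wall_s:
                    raise TimeoutError("simulation exceeded wall-clock budget")
            elif code == 1:
                self._acquisition(j, k, t)
            elif code == 2:
                self._mutant_burst(j, k, M, t)
            elif code == 4:
                raise RuntimeError(
                    f"event count exceeded guard ({self.max_events}); "
                    "runaway parameter regime")
            elif code == 5:
                raise FloatingPointError("non-finite total event rate")
        # finalize registry abundances / extinction times
        for i, sid in enumerate(self.h_ids):
            rec = self.host_rec[sid]
            rec.abundance = int(self.H[i])
            if self.H[i] == 0 and self.ext_h[i] >= 0:
                rec.t_extinct = float(self.ext_h[i])
        for i, sid in enumerate(self.v_ids):
            rec = self.vir_rec[sid]
            rec.abundance = int(self.Vab[i])
            if self.Vab[i] == 0 and self.ext_v[i] >= 0:
                rec.t_extinct = float(self.ext_v[i])
        series = TimeSeries(
            times=np.asarray(self.times),
            N=np.asarray(self.sN, dtype=np.int64),
            V=np.asarray(self.sV, dtype=np.int64),
            host_richness=np.asarray([len(d) for d in self.h_samples], dtype=np.int64),
            viral_richness=np.asarray([len(d) for d in self.v_samples], dtype=np.int64),
            host_samples=self.h_samples,
            viral_samples=self.v_samples,
        )
        tv = float(self.tot_ext[0]) if self.tot_ext[0] >= 0 else None
        th = float(self.tot_ext[1]) if self.tot_ext[1] >= 0 else None
        return RunResult(params=p, series=series, hosts=self.host_rec,
                         viruses=self.vir_rec, t_virus_extinct=tv,
                         t_host_extinct=th, n_events=self.events)


def run(params: Params, initial: Optional[SystemState] = None, *,
        max_events: int = 5_000_000_000,
        max_wall_s: Optional[float] = None) -> RunResult:
    """Simulate the model from ``initial`` (default: 100 naive hosts + 100
    identical virions) until ``params.t_max``; fully reproducible from
    ``params.seed``."""
    if initial is None:
        initial = default_initial_state(params)
    return _Engine(params, initial, max_events, max_wall_s).run()


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_timeseries(result: RunResult, path_or_buf) -> None:
    """Long-format TSV: ``time, strain_id, kind, abundance``."""
    rows = []
    s = result.series
    for i, t in enumerate(s.times):
        for sid, a in sorted(s.host_samples[i].items()):
            rows.append((t, sid, "host", a))
        for sid, a in sorted(s.viral_samples[i].items()):
            rows.append((t, sid, "virus", a))
    pd.DataFrame(rows, columns=["time", "strain_id", "kind", "abundance"]) \
        .to_csv(path_or_buf, sep="\t", index=False)


def write_totals(result: RunResult, path_or_buf) -> None:
    """Totals TSV: ``time, N, V, host_richness, viral_richness``."""
    s = result.series
    pd.DataFrame({"time": s.times, "N": s.N, "V": s.V,
                  "host_richness": s.host_richness,
                  "viral_richness": s.viral_richness}) \
        .to_csv(path_or_buf, sep="\t", index=False)


def write_phylogeny(result: RunResult, path_or_buf) -> None:
    """Phylogeny log TSV: ``strain_id, kind, parent_id, t_birth, t_extinct``."""
    rows = []
    for sid, h in sorted(result.hosts.items()):
        rows.append((sid, "host", "" if h.parent_id is None else h.parent_id,
                     h.t_birth, "" if h.t_extinct is None else h.t_extinct))
    for sid, v in sorted(result.viruses.items()):
        rows.append((sid, "virus", "" if v.parent_id is None else v.parent_id,
                     v.t_birth, "" if v.t_extinct is None else v.t_extinct))
    pd.DataFrame(rows, columns=["strain_id", "kind", "parent_id", "t_birth",
                                "t_extinct"]) \
        .to_csv(path_or_buf, sep="\t", index=False)
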