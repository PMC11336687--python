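"""Domain types for CRISPR-mediated microbe / lytic-virus coevolution.

The model tracks two co-evolving strain spaces: microbial hosts, whose
immune type is the *set* of distinct spacers accrued over their lineage's
history, and lytic viruses, whose genotype is an ordered repertoire of
``g`` protospacer loci.  Protection is identity of alleles: a host is
protected from a virus iff it carries at least one spacer matching a
protospacer in the viral repertoire.

Alleles are opaque integers issued by a single shared :class:`AlleleRegistry`
(a spacer is literally the protospacer allele it was copied from).  Under
the infinite-alleles assumption every mutation draws a fresh identifier,
so allele equality is the only matching predicate the model needs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Optional, Union

import pandas as pd

__all__ = [
    "AlleleRegistry",
    "HostStrain",
    "ViralStrain",
    "Params",
    "SystemState",
    "is_protected",
    "match_count",
    "canonicalize",
    "read_state_table",
    "write_state_table",
]


class AlleleRegistry:
    """Issues globally unique, strictly increasing allele identifiers."""

    def __init__(self, start: int = 1):
        if start < 1:
            raise ValueError("allele identifiers start at 1 or above")
        self.next_id = start

    def issue(self) -> int:
        a = self.next_id
        self.next_id += 1
        return a

    def issue_many(self, n: int) -> list[int]:
        out = list(range(self.next_id, self.next_id + n))
        self.next_id += n
        return out


@dataclass
class HostStrain:
    """A microbial immune strain: a distinct set of spacers plus abundance."""

    id: int
    spacers: frozenset[int]
    abundance: int
    parent_id: Optional[int] = None
    t_birth: float = 0.0
    t_extinct: Optional[float] = None

    def __post_init__(self) -> None:
        self.spacers = frozenset(self.spacers)
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if self.t_birth < 0:
            raise ValueError("t_birth must be non-negative")


@dataclass
class ViralStrain:
    """A viral strain: an ordered repertoire of exactly ``g`` protospacers."""

    id: int
    repertoire: tuple[int, ...]
    abundance: int
    parent_id: Optional[int] = None
    t_birth: float = 0.0
    t_extinct: Optional[float] = None

    def __post_init__(self) -> None:
        self.repertoire = tuple(self.repertoire)
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")

    @property
    def alleles(self) -> frozenset[int]:
        """Distinct alleles in the repertoire (duplicates collapse)."""
        return frozenset(self.repertoire)


@dataclass
class Params:
    """Model parameters.

    Rates are per unit time; ``phi`` is per virion per host cell.  ``q`` is
    the probability that an adsorbed host evades lysis and acquires a
    spacer; ``mu`` the per-protospacer mutation probability per replication;
    ``beta`` the burst size; ``g`` the repertoire length; ``K`` the host
    carrying capacity entering the density-dependent competition rate
    ``r*N/K``; ``w`` an optional washout (dilution) rate, zero by default so
    that cellular losses are due to lysis alone.
    """

    r: float = 1.0
    d: float = 0.1
    phi: float = 1e-7
    q: float = 1e-5
    mu: float = 5e-7
    beta: int = 50
    g: int = 15
    K: int = 100_000
    w: float = 0.0
    t_max: float = 2000.0
    sample_dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "d", "phi", "w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("q", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("beta", "g", "K"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.t_max < 0 or self.sample_dt <= 0:
            raise ValueError("t_max >= 0 and sample_dt > 0 required")


@dataclass
class SystemState:
    """Frozen snapshot of the system consumed by all analytics."""

    t: float
    hosts: list[HostStrain]
    viruses: list[ViralStrain]
    params: Params

    @property
    def N(self) -> int:
        """Total host biomass."""
        return sum(h.abundance for h in self.hosts)

    @property
    def V(self) -> int:
        """Total virion count."""
        return sum(v.abundance for v in self.viruses)


def match_count(host: HostStrain, virus: ViralStrain) -> int:
    """Number of *distinct* alleles shared between spacers and repertoire.

    A repertoire with a repeated allele matches once: matching counts
    biological matches (allele identity), not loci.
    """
    return len(host.spacers & virus.alleles)


def is_protected(host: HostStrain, virus: ViralStrain) -> bool:
    """True iff the host carries at least one matching protospacer."""
    return not host.spacers.isdisjoint(virus.alleles)


def canonicalize(state: SystemState) -> SystemState:
    """Merge duplicate genotypes and drop zero-abundance strains.

    Strains with identical genotypes are merged by summing abundances and
    keeping the earliest ``t_birth`` (and that record's id/parent).  The
    operation is idempotent.
    """

    def _merge(strains, key):
        by_geno: dict = {}
        for s in strains:
            k = key(s)
            if k in by_geno:
                keep = by_geno[k]
                if s.t_birth < keep.t_birth:
                    s, keep = keep, s
                by_geno[k] = replace(keep, abundance=keep.abundance + s.abundance)
            else:
                by_geno[k] = replace(s)
        return [s for s in by_geno.values() if s.abundance > 0]

    hosts = _merge(state.hosts, lambda h: h.spacers)
    viruses = _merge(state.viruses, lambda v: v.repertoire)
    hosts.sort(key=lambda h: h.id)
    viruses.sort(key=lambda v: v.id)
    return SystemState(t=state.t, hosts=hosts, viruses=viruses, params=state.params)


# ---------------------------------------------------------------------------
# Strain-state table I/O (TSV; exact round-trip)
# ---------------------------------------------------------------------------

_COLUMNS = ["strain_id", "kind", "genotype", "abundance", "parent_id", "t_birth"]


def _genotype_str(strain: Union[HostStrain, ViralStrain]) -> str:
    if isinstance(strain, HostStrain):
        return ",".join(str(a) for a in sorted(strain.spacers))
    return ",".join(str(a) for a in strain.repertoire)


def write_state_table(state: SystemState, path_or_buf) -> None:
    """Write one row per strain: ``strain_id, kind, genotype, abundance,
    parent_id, t_birth`` (genotype comma-separated; locus order for viruses)."""
    rows = []
    for h in state.hosts:
        rows.append((h.id, "host", _genotype_str(h), h.abundance,
                     "" if h.parent_id is None else h.parent_id, h.t_birth))
    for v in state.viruses:
        rows.append((v.id, "virus", _genotype_str(v), v.abundance,
                     "" if v.parent_id is None else v.parent_id, v.t_birth))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_state_table(path_or_buf, params: Optional[Params] = None,
                     t: float = 0.0) -> SystemState:
    """Read a strain-state table written by :func:`write_state_table`."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"genotype": str, "parent_id": "Int64"})
    hosts: list[HostStrain] = []
    viruses: list[ViralStrain] = []
    for row in df.itertuples(index=False):
        geno = str(row.genotype) if not pd.isna(row.genotype) else ""
        alleles = tuple(int(a) for a in geno.split(",")) if geno else ()
        parent = None if pd.isna(row.parent_id) else int(row.parent_id)
        if row.kind == "host":
            hosts.append(HostStrain(int(row.strain_id), frozenset(alleles),
                                    int(row.abundance), parent, float(row.t_birth)))
        elif row.kind == "virus":
            viruses.append(ViralStrain(int(row.strain_id), alleles,
                                       int(row.abundance), parent, float(row.t_birth)))
        else:
            raise ValueError(f"unknown strain kind: {row.kind!r}")
    if params is None:
        g = len(viruses[0].repertoire) if viruses else 1
        params = Params(g=g)
    for v in viruses:
        if len(v.repertoire) != params.g:
            raise ValueError(
                f"viral strain {v.id} has {len(v.repertoire)} loci, expected g={params.g}")
    return SystemState(t=t, hosts=hosts, viruses=viruses, params=params)


def state_to_tsv(state: SystemState) -> str:
    """Strain-state table as a TSV string (convenience for fixtures)."""
    buf = io.StringIO()
    write_state_table(state, buf)
    return buf.getvalue()
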