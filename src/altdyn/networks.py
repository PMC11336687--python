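"""Infection and escape networks built from a frozen system snapshot.

Three structures are derived from a canonical :class:`~altdyn.core_state.SystemState`:

* the **bipartite infection network** -- an edge (virus, host) wherever the
  host shares no allele with the viral repertoire (who infects whom);
* **viral match phenotypes** -- viruses partitioned by the subset of their
  protospacers present anywhere in the host spacer pool, with the
  susceptible biomass ``S_i`` and the ranked single-match biomasses ``A_sigma``
  each phenotype sees;
* the **tripartite escape network** -- virus-layer (phenotypes), spacer-layer
  (alleles conferring exactly one match) and host-layer nodes, whose
  spacer-node biomasses ``N_sigma`` feed the single-match diversity ``Dp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core_state import SystemState, match_count

__all__ = [
    "MatchPhenotype",
    "TripartiteNetwork",
    "InfectionNetwork",
    "build_match_phenotypes",
    "build_tripartite",
    "build_infection",
]


@dataclass
class MatchPhenotype:
    """A viral phenotype: the protospacers it shows to the host immune pool.

    ``S_i`` is the total abundance of hosts with zero matches (fully
    susceptible); ``single_matches[sigma]`` the total abundance of hosts whose
    match with the phenotype is exactly ``{sigma}`` (one escape away).
    """

    phenotype_id: int
    matched_alleles: frozenset[int]
    member_virus_ids: list[int]
    V_i: int
    S_i: int
    single_matches: dict[int, int] = field(default_factory=dict)

    @property
    def ranked_singles(self) -> list[tuple[int, int]]:
        """Single matches ``(sigma, A_sigma)`` by descending biomass, ties by
        ascending allele id."""
        return sorted(self.single_matches.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def ranked_biomasses(self) -> list[int]:
        return [a for _, a in self.ranked_singles]


@dataclass
class TripartiteNetwork:
    """Virus(phenotype)--spacer--host layers of single matches."""

    phenotypes: list[MatchPhenotype]
    spacer_biomass: dict[int, float]          # sigma -> N_sigma
    edges: list[tuple[int, int, int, int]]    # (phenotype_id, sigma, host_id, H)
    N_tri: float

    def spacer_frequencies(self) -> dict[int, float]:
        if self.N_tri <= 0:
            return {}
        return {s: b / self.N_tri for s, b in self.spacer_biomass.items()}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for ph in self.phenotypes:
            g.add_node(("phenotype", ph.phenotype_id), layer="virus",
                       abundance=ph.V_i)
        for s, b in self.spacer_biomass.items():
            g.add_node(("spacer", s), layer="spacer", biomass=b)
        for pid, s, hid, ab in self.edges:
            g.add_node(("host", hid), layer="host")
            g.add_edge(("phenotype", pid), ("spacer", s))
            g.add_edge(("spacer", s), ("host", hid), abundance=ab)
        return g

    def write_edges(self, path_or_buf) -> None:
        pd.DataFrame(self.edges, columns=["phenotype_id", "spacer_allele",
                                          "host_id", "host_abundance"]) \
            .to_csv(path_or_buf, sep="\t", index=False)


@dataclass
class InfectionNetwork:
    """Bipartite (virus strain, host strain) edges where infection can occur."""

    edges: list[tuple[int, int, int]]  # (virus_id, host_id, host_abundance)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for vid, hid, ab in self.edges:
            g.add_node(("virus", vid), bipartite=0)
            g.add_node(("host", hid), bipartite=1)
            g.add_edge(("virus", vid), ("host", hid), host_abundance=ab)
        return g

    def write_edges(self, path_or_buf) -> None:
        pd.DataFrame(self.edges, columns=["virus_id", "host_id",
                                          "host_abundance"]) \
            .to_csv(path_or_buf, sep="\t", index=False)


def build_match_phenotypes(state: SystemState) -> list[MatchPhenotype]:
    """Partition viral strains by matched-allele set against the host pool.

    Phenotype ids are assigned deterministically (sorted matched-allele
    tuples).  For each phenotype, hosts contribute their abundance to
    ``S_i`` (no match) or to ``single_matches[sigma]`` (match exactly
    ``{sigma}``); multiply-matched hosts appear in neither (protection via a
    double match is treated as escape-proof).
    """
    pool = frozenset().union(*(h.spacers for h in state.hosts)) \
        if state.hosts else frozenset()
    groups: dict[frozenset, list] = {}
    for v in state.viruses:
        groups.setdefault(v.alleles & pool, []).append(v)
    out = []
    for pid, matched in enumerate(sorted(groups, key=lambda m: tuple(sorted(m)))):
        members = groups[matched]
        S_i = 0
        singles: dict[int, int] = {}
        for h in state.hosts:
            m = h.spacers & matched
            if not m:
                S_i += h.abundance
            elif len(m) == 1:
                (sigma,) = m
                singles[sigma] = singles.get(sigma, 0) + h.abundance
        out.append(MatchPhenotype(
            phenotype_id=pid,
            matched_alleles=matched,
            member_virus_ids=sorted(v.id for v in members),
            V_i=sum(v.abundance for v in members),
            S_i=S_i,
            single_matches=singles,
        ))
    return out


def build_tripartite(state: SystemState, *, split_multi: bool = False
                     ) -> TripartiteNetwork:
    """Build the tripartite escape network.

    ``N_sigma`` aggregates the abundance of hosts singly matched via
    ``sigma`` to *any* extant phenotype (set semantics: a host counts once
    per distinct sigma even if singly matched to several phenotypes).
    ``N_tri = sum_sigma N_sigma`` therefore multi-counts hosts represented
    by several spacers, so that the frequencies ``N_sigma/N_tri`` sum to 1.
    With ``split_multi=True`` each such host's biomass is instead divided
    equally among its single-match spacers.
    """
    phenos = build_match_phenotypes(state)
    edges: list[tuple[int, int, int, int]] = []
    host_sigmas: dict[int, set[int]] = {}
    h_ab = {h.id: h.abundance for h in state.hosts}
    for ph in phenos:
        for h in state.hosts:
            m = h.spacers & ph.matched_alleles
            if len(m) == 1:
                (sigma,) = m
                edges.append((ph.phenotype_id, sigma, h.id, h.abundance))
                host_sigmas.setdefault(h.id, set()).add(sigma)
    biomass: dict[int, float] = {}
    for hid, sigmas in host_sigmas.items():
        wt = h_ab[hid] / len(sigmas) if split_multi else h_ab[hid]
        for s in sigmas:
            biomass[s] = biomass.get(s, 0.0) + wt
    return TripartiteNetwork(phenotypes=phenos, spacer_biomass=biomass,
                             edges=edges, N_tri=float(sum(biomass.values())))


def build_infection(state: SystemState) -> InfectionNetwork:
    """Edges exactly where ``match_count(host, virus) == 0``."""
    edges = [(v.id, h.id, h.abundance)
             for v in state.viruses for h in state.hosts
             if match_count(h, v) == 0]
    return InfectionNetwork(edges=edges)
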