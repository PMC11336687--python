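# Methods

## Model

`altdyn` simulates coevolution of a lytic-virus population and a microbial
host population with CRISPR-Cas immunity as a continuous-time Markov jump
process (a multi-type branching structure with density dependence),
executed exactly by Gillespie's direct method. Strains are genotypes:
a host strain is a distinct *set* of spacers (unordered, unbounded — memory
never saturates); a viral strain is an ordered repertoire of exactly `g`
protospacer loci. Alleles are opaque integers from one shared registry, so
a spacer equals the protospacer allele it was copied from and matching is
allele identity. Protospacer mutation follows the infinite-alleles
assumption: every mutation draws a never-before-seen allele.

Events and rates are listed in the README. The resolution of an adsorption
encodes the biology: the virion is always removed (protected hosts destroy
it via their matched spacer); an unprotected host evades lysis with
probability `q` and integrates the allele of one uniformly chosen locus
(re-acquiring an allele it already carries is a no-op); otherwise it is
lysed and `beta` offspring are released, each locus of each offspring
mutating independently with probability `mu`.

Assumptions worth making explicit:

- a protected host neither dies nor acquires a spacer upon adsorption;
  acquisition belongs to the lysis-evasion branch only,
- host replication is clonal and error-free; all strain birth happens at
  adsorption events,
- no spatial structure, immigration, cas-loss, or multiple CRISPR loci,
- washout `w` (density-independent host loss) is available but defaults to
  0, so host mortality is viral lysis plus density-dependent competition.

## Parameters

| name | meaning | units | default (reduced conditions) |
|---|---|---|---|
| `r` | host replication rate | 1/time | 1.0 |
| `d` | virion decay rate | 1/time | 0.1 |
| `phi` | adsorption rate | 1/(cell·virion·time) | d/(9K) ≈ 5.56e-6 |
| `q` | spacer-acquisition probability | — | 1e-3 |
| `mu` | per-protospacer mutation probability | — | 5e-5 |
| `beta` | burst size | virions | 50 |
| `g` | repertoire length | loci | 15 |
| `K` | carrying capacity | cells | 2000 |
| `w` | washout rate | 1/time | 0 |

Two non-dimensional composites organize the phase diagram: the burst size
`beta` and the maximal adsorption ratio `phi*K/d`, the number of host cells
at capacity a virion can adsorb within its lifetime. A virion's
reproductive ratio against a fully susceptible population at capacity is
`beta*(1-q)*phi*K/(d+phi*K)`; the reduced conditions pin this at 5, a
comfortably epidemic-capable virus.

`g = 15` follows the convention of strain-explicit CRISPR models of this
family; none of the derived quantities is sensitive to `g` except through
the per-offspring single-escape probability `mu*(1-mu)^(g-1) ≈ mu`.

## Reduced-scale study conditions

Every simulation-level test and the acceptance script run at
`reduced_params()`: K=2000, t_max=500, one sample per time unit, 10–20
seeds per cohort. These sizes keep a cohort under a minute while leaving
thousands of demographic events per time unit, and were chosen as the
package's standard problem size. Full-scale conditions (K ~ 1e5, q=1e-5,
mu=5e-7, t_max=2000, 50 replicates; `configs/full_scale.yaml`) produce the
same phenomenology but are cluster-scale.

At fifty-fold smaller K, the full-scale evolutionary probabilities would
yield far less than one spacer acquisition per epidemic and the dynamics
degenerate to a single immune-strain replacement. The reduced conditions
therefore raise `q` and `mu` by ~100x, keeping the *expected counts* of
acquisitions and escape mutations per epidemic at order one-to-a-few — the
same regime the full-scale conditions occupy, and the same reasoning those
conditions themselves apply (raising rates to counteract drift on the
emergence of novelty).

What the generator emulates: the alternating regime — initial epidemic,
immune rebound to K, sustained-control periods punctuated by small
single-strain outbreaks, declining host diversity and escape-pathway
diversity within control, eventual viral extinction. What it does not:
full-scale strain richness (tens, not hundreds, of host strains), multiple
long alternation cycles per run (drift at K=2000 usually ends the virus
within one or two), and any claim about real biological rate constants.
Passing cohort tests therefore demonstrates the mechanism, not
quantitative agreement with any empirical system.

## Analytics: conventions and numerical choices

**Diversity.** "Shannon diversity" is reported in Hill (effective-number)
form `exp(-sum p ln p)` throughout, matching the exponential form in which
the single-match diversity Dp is defined; raw entropy is also exposed.
Dp over an empty single-match set is NaN (undefined), never 0.

**Tripartite bookkeeping.** N_sigma sums the biomass of hosts singly
matched via sigma to *any* extant phenotype, each host counted once per
distinct sigma; N_tri = sum N_sigma consequently multi-counts hosts
represented by several spacers, so the frequencies N_sigma/N_tri sum to 1.
The alternative — dividing a host's biomass equally among its single-match
spacers — is available (`split_multi=True`). Single-match ranks are ordered
by descending biomass with ties broken by ascending allele id.

**Reproductive ratio.** R0 = beta*(1-q)*phi*S/(d + phi*N): every
adsorption removes the virion, so the removal rate in the denominator uses
total host biomass N. A susceptible-only denominator (d + phi*S) is
selectable for sensitivity analysis.

**Emergence probability.** Two routes are deliberately kept distinct. The
closed form `sigma + W0(-beta*sigma*e^(-beta*sigma))/beta` is the root of
P = sigma*(1 - e^(-beta*P)) — a Poisson-burst convention — and vanishes
exactly when R0 <= beta/(beta-1). The numerical route solves the
fixed-burst branching fixed point
eps = (1-pi) + pi*((1-l*m)*eps + m*sum_j eps_j)^beta with pi = R0/beta
(capped at 1 with a warning), m = mu*(1-mu)^(g-1), and escape lineages
terminal at first order. It is iterated from eps = 0; the map is monotone,
so the iterate converges to the minimal root. Near criticality (R0 ~ 1)
convergence slows to O(1/n); the iterate is accepted once increments fall
below 1e-9. Escape-survival terms default to the same fixed-burst fixed
point — the convention the model's lineages obey, and the one that agrees
with direct lineage simulation when a subcritical phenotype's emergence is
carried entirely by its escapes; the Lambert form for those terms is
available (`escape_survival="lambert"`) and differs by O(1/beta). The two
burst conventions differ by at most 2/beta on P\* itself.

**Expectation weighting.** ⟨P\*⟩ weights phenotypes by V_i·S_i — the
probability that the next susceptible-adsorption event involves phenotype
i — falling back to V_i when no phenotype has susceptible hosts; plain
abundance weighting is selectable. Missing escape ranks contribute a zero
reproductive differential. ⟨P\*⟩ is computed at every sample time with no
smoothing.

**Escape probability.** The closed form treats escape as mutation of the
one focal protospacer per offspring ((1-mu)^beta per burst); the
any-of-g-loci variant is exposed separately and documented as a different
quantity. Computation is in log space (log1p/expm1), stable to S ~ 1e9.
The expectation S*(1-q)*beta*mu counts all escapes, not distinct ones.

**SHC detection.** An SHC period is a maximal interval with N >= theta*K
after merging sub-threshold gaps shorter than `gap_merge` and dropping
intervals shorter than `t_min`; defaults theta=0.9, t_min=50, gap_merge=5
(robust over theta in [0.8, 0.95]). The optional `require_trough` flag
forbids periods before the first dip below threshold, guarding against
counting a near-capacity initial condition; the standard initial condition
(100 cells) starts far below threshold.

**Simulator internals.** Adsorption is drawn as one aggregate channel of
rate phi*V_tot*N_tot followed by proportional sampling of the pair, and
burst mutations as a single Binomial(beta*g, mu) count whose mutated
locus-slots are placed uniformly without replacement — both exactly
equivalent to the naive per-pair / per-Bernoulli constructions at a
fraction of the cost. The inner loop is numba-compiled; only
strain-creating events and sample boundaries return to Python, where a
cached virus-x-host protection matrix is updated incrementally. Extinct
strains are moved to an append-only phylogeny log with exact extinction
times (forward phylogenies need full history). Runs are bit-reproducible
from (params, seed) for a given backend (the numba and pure-Python
fallback RNG streams differ). A configurable event-count guard (default
5e9) and optional wall-clock budget abort runaway parameter corners.

## Known limitations

- The emergence probability freezes the host state; it describes the early
  phase of an outbreak and degrades once lysis moves the host composition
  (a time-dependent treatment is future work).
- First-order truncation in mu: an escape mutant's own further escapes are
  ignored; at mu ~ 1e-3 and above the truncation error becomes visible.
- The SHC detector is a biomass threshold; it does not use diversity or
  viral-load side conditions.
- Nestedness/modularity network statistics and distributed-immunity
  metrics are out of scope.
- Sweeps run serially; cells are seed-independent, so external
  parallelization by cell is safe.
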