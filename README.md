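# altdyn

Stochastic eco-evolutionary simulation and analysis of coevolution between
lytic viruses and microbes defended by CRISPR-Cas adaptive immunity.

Microbial hosts store fragments of viral genomes (spacers) and are protected
from any virus carrying a matching protospacer. Hosts diversify by spacer
acquisition; viruses diversify by protospacer mutation under an
infinite-alleles assumption. Together with host density-dependent
competition, these ingredients generate *alternating dynamics*: transient
periods of sustained host control (SHC), in which host biomass saturates
near carrying capacity and rare viral strains drift to extinction, punctuated
by major viral epidemics (MVE) with rapid host–virus co-diversification,
until the viral population finally goes extinct. `altdyn` is for modellers
studying when host control forms, why it becomes fragile, and which
non-dimensional parameters govern the alternations.

## Model

Continuous-time Markov jump process, simulated exactly with Gillespie's
direct method over a dynamic strain space. For host strain *k* (abundance
H<sub>k</sub>, spacer set **s**<sub>k</sub>) and viral strain *j* (abundance
V<sub>j</sub>, repertoire of *g* protospacer loci), with N = Σ H<sub>k</sub>:

| event | rate |
|---|---|
| host replication (clonal) | r·H<sub>k</sub> |
| density-dependent death | r·(N/K)·H<sub>k</sub> |
| washout (optional) | w·H<sub>k</sub> |
| virion decay | d·V<sub>j</sub> |
| adsorption | φ·V<sub>j</sub>·H<sub>k</sub> |

Adsorption always consumes the virion. A protected host (shared allele)
destroys it; an unprotected host acquires one protospacer as a spacer with
probability q (creating a new immune strain), otherwise it is lysed,
releasing β virions whose loci each mutate to a brand-new allele with
probability μ.

On top of frozen snapshots the package derives the analytics used to
dissect the dynamics:

- **Networks** — the bipartite infection network (who infects whom) and the
  tripartite virus–spacer–host escape network of single matches.
- **Diversity** — Hill–Shannon diversity of host strains and the
  single-match diversity
  D<sub>p</sub> = exp(−Σ<sub>σ</sub> (N<sub>σ</sub>/N<sub>tri</sub>)
  ln(N<sub>σ</sub>/N<sub>tri</sub>)), the effective number of escape
  pathways protecting host biomass.
- **Emergence** — per match phenotype *i*, the reproductive ratio
  R<sub>0</sub><sup>i</sup> = β(1−q)φS<sub>i</sub>/(d+φN), ranked escape
  ratios R<sub>j</sub><sup>i</sup>, and the emergence probability
  P\* = σ + W<sub>0</sub>(−βσe<sup>−βσ</sup>)/β (σ = R<sub>0</sub>/(R<sub>0</sub>+β),
  principal Lambert branch) together with a numerical multi-type branching
  fixed point carrying the O(μ) contribution of single-match escapes; the
  infection-weighted expectation ⟨P\*⟩ anticipates outbreak onsets.
- **Escape probability** — P<sub>S</sub>(n<sub>e</sub>≥1) =
  1−(q+(1−q)(1−μ)<sup>β</sup>)<sup>S</sup>, maximized at S = K.
- **SHC detection and sweeps** — threshold-based detection of host-control
  periods and replicate grids over the non-dimensional axes (β, φK/d) and
  (q, μ).

## Worked example

```python
from altdyn import run, summarize_run
from altdyn.experiments import reduced_params, analyze_run

params = reduced_params(seed=0)      # K=2000, beta=50, q=1e-3, mu=5e-5, ...
result = run(params)
summary = summarize_run(result)
table = analyze_run(result)          # per-sample diversity + emergence
```

For seed 0 this prints (via the obvious `print` statements):

```
events simulated     : 2998586
SHC periods          : 1  durations ['381']
viral extinction at  : t = 358.7
peak viral abundance : 190278
host strains created : 25   viral strains: 859
at t=120: N=2000  host Hill diversity=3.46  Dp=5.17  <P*>=0.0015  <R0>=0.12
```

Reading: the initial epidemic (peak ~1.9×10⁵ virions) lyses most naive
hosts; immune strains rebound to carrying capacity (N = 2000) and hold a
single 381-time-unit control period during which the effective number of
host strains is ~3.5 and ~5 escape pathways protect the biomass. Small
outbreaks during control are heralded by spikes of ⟨P\*⟩ above its ambient
~10⁻³ level; the virus goes extinct at t ≈ 359.

The same machinery is exposed on the command line:

```sh
altdyn simulate --config src/altdyn/configs/reduced.yaml --seed 7 --out out/
altdyn escape-curve --q 1e-5 --mu 5e-7 --beta 50 --K 100000 --smax 100000 --out curve.tsv
altdyn detect-shc --totals out/totals.tsv --K 2000 --out shc.tsv
```

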