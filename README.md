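# mitopop

Mitochondrial phylogeography toolkit for haplotype-level population
analysis: diversity and neutrality statistics, mismatch-distribution
expansion models, pairwise F_ST / isolation-by-distance inference,
median-joining haplotype networks, and molecular-rate calibration with
expansion dating — the complete analysis chain of a marine mtDNA survey,
as applied to the Macaronesian *Octopus vulgaris* control-region dataset
(six NE-Atlantic sampling sites, two deeply divergent haplogroups with
opposing latitudinal clines).

It is written for population geneticists who want that chain as a scriptable
Python library rather than a sequence of GUI tools (Arlequin, Network,
IBD): every statistic is a plain function over explicit containers
(`Alignment`, `HaplotypeTable`, `DistanceMatrix`), every stochastic step
takes a seed, and a coalescent generator produces study-shaped synthetic
datasets with truth labels so the whole chain can be validated end to end.

## The statistics at the core

* **Diversity** — haplotype diversity `h = n(1 − Σp_i²)/(n − 1)` (Nei),
  nucleotide diversity `π = θ̂_π/L` from mean pairwise differences,
  Watterson's `θ_S = S/a_1`.
* **Neutrality** — Tajima's `D = (θ̂_π − θ̂_S)/√(e₁S + e₂S(S−1))`; Fu's
  `F_S = ln(S′/(1 − S′))` with `S′ = P(K ≥ k_obs | θ̂_π, n)` under the Ewens
  sampling distribution, computed through a log-space Stirling-number
  recurrence.  P-values by neutral constant-size coalescent simulation.
* **Demography** — observed mismatch distributions against closed-form
  sudden (`τ, θ₀, θ₁`) and spatial (`τ, θ, M`) expansion laws; SSD
  least-squares fitting with parametric-bootstrap goodness of fit and
  Harpending's raggedness.
* **Structure** — two-population AMOVA `F_ST = σ²_a/(σ²_a + σ²_w)`
  (haplotype identity, or Φ_ST with difference weighting) with
  specimen-permutation P-values; Slatkin linearization `F/(1 − F)`
  regressed on `ln(km)` (great-circle) plus a Mantel matrix test.
* **Networks** — median-joining: minimum spanning network (union of all
  MSTs) plus consensus median vectors; haplogroups by longest-bridge cut.
* **Dating** — geminate-clade rate `μ = d_net/(2T)`; θ-ratio rate transfer
  between loci (`μ_CR = μ_COX1 · θ_CR/θ_COX1`); expansion age
  `t = τ/(2μL)` years.

## Worked example

```python
from mitopop import (SimulationConfig, simulate_dataset, collapse_haplotypes,
                     median_joining, assign_haplogroups)

ds = simulate_dataset(SimulationConfig(seed=2024))   # 296 x 637 sites
ht = collapse_haplotypes(ds.alignment)
net = median_joining(ht)
groups = assign_haplogroups(net, ht)
print(ht.k, groups["group_frequencies"])
```

prints

```
21 {'alpha': 0.5, 'beta': 0.5}
```

— 21 distinct haplotypes, and the longest-bridge cut of the network splits
the specimens 50/50 between the two simulated haplogroups (100% agreement
with the generator's truth labels; `examples/04_network_haplogroups.py`
scores this explicitly).  The other scripts in `examples/` walk one
capability each — simulation, diversity/neutrality tables, F_ST + IBD,
mismatch fitting, and the dating chain, which prints:

```
theta ratio CR/COX1 = 12.317/3.486 = 3.53
mu_CR = 5.44e-08 subs/site/year
haplogroup alpha spatial  tau=4.114 -> 59.4 Kya
haplogroup beta  sudden   tau=1.191 -> 17.2 Kya
haplogroup beta  spatial  tau=0.781 -> 11.3 Kya
```

placing the older haplogroup's expansion before the last glacial maximum
and the younger one's in the post-glacial recolonization window.

A thin CLI wraps the chain end to end: `mitopop simulate`, `mitopop report`,
`mitopop printed` (published-table mode).

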