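# admixscreen

Simulation-based evaluation of qpAdm / qpWave admixture screening.

High-throughput qpAdm protocols — screens that test every combination of
proxy sources for a target population against a panel of "right" reference
groups — are a workhorse of archaeogenetics, yet their false discovery
rates on realistically complex histories are hard to intuit. This package
provides everything needed to measure them end to end on synthetic data:

* **Synthetic histories.** Random dated admixture graphs (13 populations,
  10 pulse admixture events, 20–120-generation event spacing, graph depth
  800 or 3000 generations) and 64-deme hexagonal stepping-stone landscapes
  with era-structured, direction-asymmetric gene flows in four intensity
  regimes, both simulated to genotypes with msprime and optionally degraded
  to pseudohaploid, missingness-rich archaeogenetic data quality.
* **Inference core.** Block-resolved f2/f3/f4 statistics (from-f2 and
  "allsnps" modes), weighted block-jackknife errors, Hudson FST, and an
  independent qpWave/qpAdm implementation: the rank of the f4 matrix
  `x_ij = f4(l1, l_i; r1, r_j)` is tested by a generalised-least-squares
  fit under the jackknife covariance, and admixture weights (EAF, summing
  to 1 but not confined to [0, 1]) are the left null vector of the fitted
  rank-(n−1) matrix, with delete-one-block standard errors.
* **Screening protocols.** Rotating / nonrotating and distal / proximal
  screens, randomized and systematic landscape sampling, the grid of 36
  composite feasibility criteria (EAF conditions × P-value thresholds ×
  trailing-model rules), experiment progression from 1-way upward, and
  model competition.
* **Evaluation.** Spatial model-optimality metrics (source–target
  distances in lattice steps, minimal source–target–source angles,
  distance to the ideal symmetric model), prestudy odds R and
  `FDR = FPR/(R − FNR·R + FPR)`, a topological true/false-positive
  classifier for graph histories, the misleading-experiment rule, PCA and
  ancestry-component support rules, and a geographic variant (great-circle
  distances, bearing angles) for published model tables with real
  coordinates.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

Fit a 2-way qpAdm model on a simulated history in which the target `T` is
a 30/70 mixture of the lineages represented by the sampled proxies `S1b`
and `S2b`, with four rights chosen to be differentially related to the two
sides:

```python
import numpy as np
from tests.conftest import pulse_recovery_graph   # or build your own graph
from admixscreen.ags import simulate_ags_genotypes
from admixscreen.fstats import compute_f2_blocks
from admixscreen.qpadm import fit_qpadm

graph = pulse_recovery_graph()
data = simulate_ags_genotypes(
    graph, n_chrom=2, chrom_len=10_000_000, seed=100, samples_per_leaf=5
)
blocks = compute_f2_blocks(data, blgsize=500_000)
res = fit_qpadm("T", ("S1b", "S2b"), ("O", "O2", "R1", "R2"), blocks)
print(f"P = {res.p_value:.3f}")
print("weights", np.round(res.weights, 3), "+-", np.round(2 * res.se, 3))
```

prints

```
P = 0.212
weights [0.321 0.679] +- [0.068 0.068]
```

The model is not rejected (P = 0.21 ≥ 0.01), and the estimated admixture
fractions recover the simulated 0.30/0.70 within two standard errors —
the composite feasibility criterion used for graph histories (trailing
1-way models rejected at P < 0.01, EAF ± 2 SE inside (0, 1), model
P ≥ 0.01) would call this model feasible.

A command-line surface wraps the simulators and the core
(`admixscreen ags simulate`, `admixscreen ssl simulate`,
`admixscreen fstats f4`, `admixscreen qpadm`, `admixscreen screen-plan`,
`admixscreen geo-metrics`); genotypes are exchanged as EIGENSTRAT
`.geno/.snp/.ind` triples.

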