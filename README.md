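# scovnet

Structural covariance network analysis for morphometric group studies.

Neuroimaging group studies often summarize anatomy as one number per atlas
region per subject (for example gray-matter volume in the 90 cerebral
regions of the AAL parcellation). A **structural covariance network** treats
those regions as nodes and connects the pairs whose values co-vary most
strongly across the subjects of a group, after removing nuisance covariates
(age, sex, total intracranial volume). `scovnet` builds these networks,
measures their topology, and tests whether two groups differ — the workflow
used throughout clinical covariance-network studies, packaged as a tested,
reproducible library and command line.

The pipeline:

1. **Residualize** each region on [1, age, sex, TIV] within the group.
2. **Correlate** residuals across subjects → Pearson matrix `r` (N × N).
3. **Threshold** at each density `d` of a grid (default 0.10:0.02:0.50):
   keep the K = round(d·N(N−1)/2) strongest pairs, binarize.
4. **Measure**: clustering Cp, characteristic path length Lp, global and
   local efficiency, and normalized nodal betweenness; γ = Cp/Cp_rand,
   λ = Lp/Lp_rand and the small-world index σ = γ/λ against 20
   degree-preserving (Maslov–Sneppen) null networks.
5. **Resilience**: relative giant-connected-component size under random
   failure and targeted (betweenness- or degree-ranked) attack.
6. **Inference**: permutation tests (subjects reassigned to pseudo-groups,
   the whole pipeline re-run) per density, on trapezoidal area-under-curve
   (AUC) summaries across the grid, per region, and per removal count.

Because real morphometry tables are rarely shareable, the package includes
a first-class synthetic-cohort generator with known ground-truth covariance
topology (multivariate normal with edge-structured correlation, covariate
effects, and noise), so every stage can be validated against closed-form
oracles. See `docs/methods.md` for the model, conventions and caveats.

## Worked example

```python
import numpy as np
from scovnet import (DensityGrid, generate_paired_cohorts, make_null_ensemble,
                     correlation_matrix, residualize, threshold_by_density,
                     small_world)
from scovnet.inference import PermutationConfig, run_global_comparison
from scovnet.synthetic import preset_pair

# Two 31-subject groups; group B's generating graph has its lattice edges
# fully rewired, destroying clustering at equal density.
spec_a, spec_b = preset_pair("reduced_clustering", seed=0)
cohort_a, cohort_b = generate_paired_cohorts(spec_a, spec_b, 31, 31)

r = correlation_matrix(residualize(cohort_a))
net = threshold_by_density(r, 0.10)
ens = make_null_ensemble(net.adjacency, n_nulls=20, seed=1)
gm = small_world(net.adjacency, ens)
print(f"group A at density 0.10: Cp={gm.cp:.3f}  Lp={gm.lp:.3f}  "
      f"gamma={gm.gamma:.2f}  lambda={gm.lambda_:.2f}  sigma={gm.sigma:.2f}")

cfg = PermutationConfig(n_perm=200, n_nulls=0,
                        densities=DensityGrid(0.10, 0.50, 0.10), seed=42)
gc = run_global_comparison(cohort_a, cohort_b, cfg)
for m in ("cp", "lp", "e_glob", "e_loc"):
    res = gc.auc[m]
    print(f"{m:6s} AUC diff (A-B) = {res.diff:+.4f}   p = {res.p_value:.3f}")
```

Output:

```
group A at density 0.10: Cp=0.470  Lp=2.785  gamma=4.64  lambda=1.22  sigma=3.81
cp     AUC diff (A-B) = +0.0255   p = 0.010
lp     AUC diff (A-B) = +0.0239   p = 0.010
e_glob AUC diff (A-B) = -0.0031   p = 0.010
e_loc  AUC diff (A-B) = +0.0172   p = 0.010
```

Group A's covariance network is strongly small-world (σ = 3.8 ≫ 1: much
more clustered than degree-matched random networks at comparable path
length). Against group B the permutation AUC tests recover the built-in
effect: A has higher clustering and local efficiency across the density
range, with correspondingly longer paths and slightly lower global
efficiency, all at the smallest attainable p for 200 permutations
(p = 2·(0+1)/(200+1) ≈ 0.01).

## Command line

```sh
scovnet simulate --n 31 --seed 7 --group-label hc --out data/
scovnet build --cohort data/hc_values.csv --covariates data/hc_covariates.csv \
              --densities 0.10:0.02:0.50 --out net_hc/
scovnet metrics --network net_hc/ --nulls 20 --seed 11
scovnet resilience --network net_hc/ --strategy betweenness
scovnet compare --cohort-a a.csv --covariates-a a_cov.csv \
                --cohort-b b.csv --covariates-b b_cov.csv \
                --densities 0.10:0.02:0.50 --n-perm 1000 --seed 42 --out results/
scovnet report --results results/       # difference and resilience plots
```

`compare` writes tidy CSV tables (per-density metric differences with
permutation bands and significance, an AUC table, a per-region betweenness
table, resilience curves) plus a run-metadata YAML recording every seed;
identical configurations reproduce every output byte-for-byte.

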