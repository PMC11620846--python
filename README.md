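# coexistkit

Quantitative community ecology for quadrat survey data: who dominates a
shrub layer, how species partition environmental gradients, whether they
co-occur more or less than chance, and which environmental factors drive
the pattern.  The package was built around a survey of the shrub layer of
island *Pinus massoniana* communities (40 plots × 4 quadrats, 9 soil
chemistry variables, topography, isolation and climate) and ships that
study's published summary tables as fixtures, but every stage is generic.

## What it computes

- **Importance values** — IV% = (relative abundance + relative frequency
  + relative coverage)/3 per species and plot, with dominant-species
  screening (mean IV > 1%).
- **Niche metrics** — Shannon breadth B_S = −Σ P_ij ln P_ij and Pianka
  overlap O_ik = Σ P_ij P_kj / √(Σ P_ij² Σ P_kj²) over binned gradient
  levels or over the plots themselves.
- **Association tests** — Schluter's variance ratio VR = S_T²/δ_T² with
  W = N·VR against χ² bounds; Yates-corrected χ² per species pair;
  Pearson and Spearman abundance correlations with significance classes.
- **Phylogenetic structure** — mean pairwise patristic distance (MPD) and
  the net relatedness index NRI = −(MPD_obs − mean MPD_null)/sd MPD_null
  under a taxa-shuffle null.
- **Environmental interpretation** — correlation-matrix PCA of soil
  variables; RDA with greedy forward selection and Monte-Carlo
  permutation tests; the 11 classical bivariate regression families with
  IQR-based outlier screening.
- **Synthetic communities** — Gaussian niche responses with Poisson
  counts and Brownian-conserved optima on a simulated phylogeny, so every
  statistic can be checked against planted ground truth.

## Worked example

```python
import coexistkit as ck

# Published niche-overlap matrix of the 23 dominant shrub species
m = ck.load_fixture("overlap_matrix")
s = ck.overlap_summary(m)
print(f"{s['n_pairs']} pairs; {s['n_ge']} with O >= 0.5 ({s['pct_ge']:.2f}%); "
      f"mean {s['mean']:.2f}, range {s['min']:.2f}-{s['max']:.2f}")

# Soil-chemistry ordination of the 40 survey plots
res = ck.pca_rank(ck.load_fixture("soil"))
print(f"PC1 eigenvalue {res.eigenvalues[0]:.4f} "
      f"({100*res.proportion_explained[0]:.2f}%), "
      f"first two axes {100*res.cumulative_proportion[1]:.2f}%")

# A synthetic community with niche structure, analysed end to end
from coexistkit import (SimulationConfig, simulate_community,
                        compute_importance, to_presence, variance_ratio_test)
cfg = SimulationConfig(seed=1, brownian_rate=1.0)
records, envs, tree, truth = simulate_community(cfg)
iv = compute_importance(records)
vr = variance_ratio_test(to_presence(iv.iv_matrix))
print(f"{len(records)} records; VR = {vr.vr:.2f}, W = {vr.w:.2f} "
      f"(bounds {vr.lower:.2f}, {vr.upper:.2f}) -> {vr.verdict}")
```

prints

```
253 pairs; 87 with O >= 0.5 (34.39%); mean 0.42, range 0.02-0.83
PC1 eigenvalue 2.8498 (31.66%), first two axes 50.49%
2217 records; VR = 2.97, W = 118.73 (bounds 26.51, 55.76) -> significant-positive
```

The first line says 87 of the 253 dominant-species pairs overlap
substantially in resource use; the second that the leading soil axis
carries 31.66% of soil variation (first two > 40%, so the ordination is
acceptable by the usual rule); the third that the simulated community —
whose species share Brownian-conserved gradient optima — shows the
expected significant positive overall association (W far above the upper
χ² bound).

## Command line

A thin CLI wraps the library:

```sh
coexistkit importance --records records.csv --out iv.csv
coexistkit assoc --records records.csv --out pairs.csv,summary.csv
coexistkit nri --presence presence.csv --tree tree.nwk --nrand 999 --seed 42 --out nri.csv
coexistkit pca --env env.csv --vars pH,t_k,a_k,t_p,a_p,t_n,a_n,som,salt --out pca.csv
coexistkit rda --iv iv.csv --env env.csv --nperm 499 --seed 7 --out rda.csv
coexistkit simulate --seed 42
coexistkit run --config pipeline.yaml
```

`coexistkit run` executes the full pipeline (importance → screening →
niche → association → NRI → PCA/RDA) and writes CSV report surfaces, a
markdown summary and a run log; identical config and seed give
byte-identical outputs.

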