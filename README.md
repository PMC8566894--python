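# commassembly

Inference of microbial community-assembly processes from marker-gene
survey data: how much of the variation among communities is stochastic
(drift, random immigration, ecological equivalence) and how much is
deterministic (environmental selection), and which environmental drivers
carry the deterministic part.

The package is written for amplicon-scale datasets — an OTU table
(samples × taxa counts), a rooted phylogeny of the taxa, and sample
metadata — and was built around surveys of single functional guilds
(e.g. *nifH*-amplified diazotroph communities), where a few dominant
taxa and strong dominance skew are the norm. Because the question "was
this community assembled neutrally?" has no ground truth in field data,
the package ships a first-class synthetic-community generator (neutral
Moran drift, Gaussian niche filtering on a Brownian trait, multinomial
sequencing) so every inference stage is validated by parameter recovery.

## What it computes

| Stage | Statistic | Reading |
|---|---|---|
| `ncm` | Sloan neutral model fit: `freq(p) = 1 − I_d(Nm·p, Nm(1−p))` | migration `m`, fit `R²`, per-taxon above/within/below partition |
| `stegen` | βMNTD, βNTI (999 tip-shuffling nulls), RC_Bray (999 probabilistic nulls) | per-pair process: variable selection (βNTI > +2), homogeneous selection (βNTI < −2), dispersal limitation (RC > +0.95), homogenizing dispersal (RC < −0.95), undominated |
| `nst` | normalized stochasticity ratio over 6 bounded metrics × 2 null algorithms | NST > 50 % = stochastic-dominated; permutational ANOVA between groups |
| `phylosignal` | Blomberg's K of realized niche values + PIC permutation test | K ≈ 1 Brownian conservatism, K ≈ 0 no signal |
| `diversity` | richness, Chao1, ACE, Shannon, Pielou, Gini–Simpson; Bray/Jaccard/Kulczynski/Gower/Manhattan/Canberra | alpha and beta structure |
| `drivers` | Mantel, PERMANOVA, thresholded Spearman co-occurrence network (\|r\| > 0.5, p < 0.05) with node topology | which environmental axes and taxon modules carry the signal |

The formulas, conventions and calibration results are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a neutral community survey (20 samples, 100 taxa, migration
m = 0.5) and run the three core inferences:

```python
from commassembly.synth import SimulationConfig, simulate_dataset
from commassembly.ncm import fit_ncm
from commassembly.stegen import beta_nti, rc_bray, classify_processes
from commassembly.nst import nst

ds = simulate_dataset(SimulationConfig(regime="neutral", n_samples=20,
                                       n_taxa=100, m=0.5, seed=42))

fit = fit_ncm(ds.matrix)
print(f"NCM: m = {fit.m:.3f}, R^2 = {fit.r_squared:.3f}")

bnti = beta_nti(ds.matrix, ds.tree, n_null=999, seed=1)
rc = rc_bray(ds.matrix, n_null=999, seed=2)
for label, frac in classify_processes(bnti, rc).fractions.items():
    print(f"{label:>22}: {100 * frac:5.1f}%")

res = nst(ds.matrix, metric="bray", n_null=999, seed=3)
print(f"NST (Bray-Curtis): {100 * res.nst:.1f}%")
```

which prints

```
NCM: m = 0.335, R^2 = 0.948
    variable_selection:   0.5%
 homogeneous_selection:   1.1%
  dispersal_limitation:   0.0%
homogenizing_dispersal:   0.5%
           undominated:  97.9%
NST (Bray-Curtis): 88.9%
```

Read: the occupancy–abundance curve is well explained by the neutral
model (R² = 0.95) with a substantial migration estimate; 97.9 % of sample
pairs show neither a selection signal (|βNTI| ≤ 2) nor a strong dispersal
signal (|RC| ≤ 0.95); and the stochasticity ratio sits far above the 50 %
boundary — all three lines of evidence agree with the (true) neutral
assembly of this dataset. Running the same stack on a two-optima
selection regime (`regime="variable_selection", sigma_w=0.5`) drops NST
below 15 % and fills the variable-selection / dispersal-limitation
classes instead.

## Analyses

`analysis/` contains the numbered end-to-end analyses, each a thin driver
over the library that prints what it finds and writes tables under
`results/`:

```sh
python analysis/01_simulate_communities.py --seed 1   # four ground-truth regimes
python analysis/02_diversity_summary.py               # alpha/beta structure
python analysis/03_fit_neutral_model.py               # NCM per regime
python analysis/04_null_model_classification.py       # βNTI + RC_Bray fractions
python analysis/05_stochasticity_ratio.py             # NST table
python analysis/06_phylogenetic_signal.py             # Blomberg's K
python analysis/07_driver_network.py                  # Mantel, PERMANOVA, network
```

A `commassembly` command-line interface exposes the same stages
(`simulate`, `diversity`, `ncm`, `stegen`, `nst`, `signal`, `network`,
`run`); `commassembly run config.yaml` executes the whole pipeline from a
validated YAML config with one global seed.

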