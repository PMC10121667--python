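# tmakit

Spatial, transcriptomic and survival analysis of immune/hypoxia markers
on tissue-microarray (TMA) cores.

## The problem

In many solid tumors, hypoxia appears to exclude cytotoxic CD8+ T cells
from the tumor microenvironment. On immunostained TMA cores, each
detected cell is a point with a phenotype label — e.g. CD8+ T cells and
CAIX+ (carbonic anhydrase IX, a hypoxia surrogate) cells — and a
tumor/stroma compartment. `tmakit` provides the statistical machinery
to ask, at several scales, whether the two phenotypes co-occur or avoid
each other, and whether either predicts survival:

* **cell scale** — the cross-type Ripley K function
  `K_ij(d) = E[# type-j cells within d of a typical type-i cell] / λ_j`,
  estimated per core with translation edge correction and compared with
  its independence benchmark `πd²` via pointwise Monte Carlo envelopes
  (random-labeling or conditional-CSR nulls; 99% bands from 199
  simulations), aggregated family-wise across cores by per-distance
  min/max, with a density filter for evaluable cores;
* **core scale** — Spearman correlation of CD8/CAIX densities with
  percentile-bootstrap CIs, and negative-binomial / zero-inflated
  Poisson regression of CD8 counts on CAIX density with a log-area
  offset and a TMA×CAIX interaction, compared by AIC;
* **cohort scale** — expression matrices scored for hypoxia by ssGSEA
  (weighted rank running sum, α = 0.75) and correlated with log CD8A;
* **patient scale** — Kaplan–Meier/log-rank, tertile categorization at
  the 34th/66th percentiles, multivariable Cox proportional hazards
  (Newton–Raphson, Efron or Breslow ties) with martingale/deviance
  residuals, leave-one-out influence, a Kolmogorov-type supremum test
  of proportionality, and simulation-based post-hoc power.

Every input can also be *simulated* with known ground truth
(`tmakit.synthetic`): marked point patterns on disc cores with
controllable attraction/repulsion and compartment masks, censored
cohorts from a Weibull-baseline Cox model (default CD8-density log
hazard ratio −0.026, i.e. HR 0.974 per unit density), and expression
matrices with a latent hypoxia factor. This makes every stage testable
end-to-end: parameter recovery, envelope coverage, test sizes.

The intended users are biostatisticians and computational pathologists
working with per-cell exports from digital-pathology tools (QuPath-style
CSV tables) plus clinical follow-up data.

## Worked example

Run the end-to-end synthetic pipeline with a repulsion ground truth
(CAIX+ cells delete nearby CD8+ cells with probability 1 within 40 µm):

```python
from tmakit.io import RunConfig, run_pipeline

cfg = RunConfig(
    seed=42, out_dir="demo_run", n_subjects=40,
    core=dict(interaction="repulsion", interaction_radius=40.0,
              interaction_strength=1.0, lambda_i=3e-4, lambda_j=5e-4,
              lambda_bg=2e-4),
)
res = run_pipeline(cfg)
print(res["association"].round(4))
print(res["cox"].summary().round(4).loc[["cd8_density", "caix_density"]])
```

which prints (seed 42):

```
  compartment     rho   p      lo      hi
0         all -0.6017 0.0 -0.7364 -0.4237
1       tumor -0.4997 0.0 -0.6490 -0.3136
2      stroma -0.5321 0.0 -0.6792 -0.3316

                coef      se      hr   hr_lo   hr_hi       p
cd8_density  -0.0614  0.0239  0.9404  0.8974  0.9856  0.0102
caix_density -0.0410  0.0245  0.9598  0.9149  1.0070  0.0943
```

Reading this: the repulsion truth shows up as a clearly negative
core-level Spearman correlation between CAIX and CD8 densities (overall
−0.60 with 95% bootstrap CI (−0.74, −0.42), and similarly within
stroma), and the fitted Cox model estimates a protective CD8-density
effect (HR 0.94 per cells/mm², p = 0.01) on the simulated survival
times. The negative-binomial fit on the same run estimates a negative
CAIX effect on CD8 counts (−2.16×10³ per cells/µm², p = 7×10⁻⁴).
`demo_run/` contains the per-cell table, per-core summaries, tidy
cross-K + envelope curves, fit tables, cohort and a JSON manifest that
fully determines the outputs (rerunning with the same seed is
byte-identical).

The same operations are scriptable from the shell:

```sh
tmakit simulate core --seed 1 --n-cores 4 --out sim
tmakit spatial crossk --cells sim/cells.csv --nsim 199 --level 0.99 --seed 2 --out k
tmakit simulate cohort --seed 3 --out coh
tmakit survival fit --cohort coh/cohort.csv --out fit
```

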