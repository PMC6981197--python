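# lineagediv

Community phylogenetics of tree communities along precipitation gradients:
does the evolutionary diversity of communities peak at intermediate rainfall?

`lineagediv` implements, as a tested and reusable pipeline, the chain of
inference from a genus-level time-calibrated phylogeny, a site-by-genus
incidence matrix and a site climate table to that question:

1. **Genus climate niches** — each genus's niche is the mean annual
   precipitation (MAP, mm/yr) averaged over its occupied sites.
2. **Phylogenetic signal** — Pagel's λ for the niches by maximum likelihood
   on [0, 1], where λ scales the off-diagonal of the Brownian-motion
   covariance **C**: trait ~ MVN(μ·**1**, σ²·C(λ)); significance by a
   likelihood-ratio test against λ = 0.
3. **Lineage diversity (LD)** — the standardized effect size of Faith's
   phylogenetic diversity, LD = (PD_obs − mean PD_null) / sd PD_null, with
   the null built by randomly shuffling the tip labels of the whole
   phylogeny. Missing genera can be grafted at random positions inside
   their most derived consensus clades (MDCCs); wet communities can be
   rarefied to a fixed genus count as a richness control; LD can be
   averaged across a set of trees.
4. **Model competition** — linear, quadratic, and piecewise (two
   independent lines split at an estimated break point, no continuity
   constraint) regressions of LD on MAP, compared by AIC; each side of the
   break is refit by generalized least squares with exponential, Gaussian,
   linear or spherical residual correlation decaying with great-circle
   distance, the range estimated by profile maximum likelihood; 99%
   mean-prediction bands.
5. **Conservation ranking** — unprotected sites ranked by LD; the top
   fraction reported.

Because the community database and phylogeny that motivate this design are
not bundled, the package ships a first-class synthetic-data generator
(`lineagediv.simulate`) that reproduces the assumed statistical structure —
an ultrametric birth–death genus tree, niches with intermediate
phylogenetic signal (λ ≈ 0.5), niche-filtered presence/absence communities
along a 300–3,500 mm MAP gradient, and spatially autocorrelated site
noise — so every downstream stage is testable end to end. Its `ech` preset
encodes the environmental-crossroads scenario (young dry-adapted and
wet-specialist clades at the climatic extremes); the `null` preset
assembles communities with no niche filtering and is the negative control.

## Worked example

```bash
lineagediv run --preset ech --n-tips 300 --n-sites 200 --n-null 199 \
    --seed 11 --out results/demo
```

prints

```json
{
  "selected_kind": "piecewise",
  "break_point": 2650.917104560645,
  "lambda_hat": 0.8127023516818611,
  "outdir": "results/demo"
}
```

The genus niches carry strong phylogenetic signal (λ̂ = 0.81; the preset's
clade-structured pools add signal beyond the λ_true = 0.5 Brownian
component), the piecewise model beats the quadratic and linear
alternatives by AIC, and the fitted break point (≈ 2,651 mm) falls
strictly between the preset's dry (800 mm) and wet (3,200 mm) pool
means — lineage diversity peaks at intermediate precipitation, as the
crossroads scenario predicts. `results/demo/` contains the LD table,
model-comparison table, 99% confidence band, and conservation ranking.

The same story, told step by step with intermediate tables, lives in the
numbered drivers:

```bash
python analysis/01_simulate.py          # synthetic studies (ech + null)
python analysis/02_phylogenetic_signal.py
python analysis/03_lineage_diversity.py # sesPD + rarefaction control
python analysis/04_model_competition.py # OLS + spatial GLS + 99% bands
python analysis/05_robustness.py        # MDCC grafting, tree-set LD
python analysis/06_conservation.py      # top 5% unprotected sites
```

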