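# limbmorph

Limb-bone ecomorphology in Python: how do body size and locomotor ecology
shape the **external form** and **internal structure** of long bones, once
shared evolutionary history is accounted for?

Mammal clades that dig, climb, or glide leave signatures in their humeri and
femora — in overall bone shape, and in cross-sectional properties of the
diaphysis that govern resistance to bending, torsion, and compression.
`limbmorph` implements the full analysis chain for testing such hypotheses
on a clade of species with CT-scanned bones, 3-D landmark data, and a
time-calibrated phylogeny, plus a synthetic-data generator so every stage
can be validated against known ground truth without any scans.

## What it computes

**Bone structure** (`limbmorph.structure`) — from a binary voxel volume,
slice-by-slice proximodistal profiles (material cross-sectional area,
hole-filled total area, compactness, principal second moments of area), and
three whole-bone traits over the middle 40% of functional length *L*:

- **Cg** (global compactness) — mean of slice CSA / total area,
- **DE** (diaphysis elongation) — *L* / √(midshaft CSA),
- **CSS** (cross-sectional shape) — I_major / I_minor at the midshaft
  (1 = circular; larger = more elliptical).

**Geometric morphometrics** (`limbmorph.morphometrics`) — Generalized
Procrustes Analysis with centroid size, shape PCA / phylomorphospace,
Procrustes ANOVA/ANCOVA with residual-randomization permutation (RRPP) tests
with or without a phylogenetic (Brownian or Pagel-λ) transform, Pillai's
trace MANOVA, pairwise least-squares-mean tests, two-block partial least
squares, and canonical variate analysis with jackknife cross-validation.

**Phylogenetic comparative models** (`limbmorph.phylo`) — univariate PGLS
`y = Xβ + ε`, `ε ~ N(0, σ²C(λ))`, with Pagel's λ estimated jointly with β
by maximum likelihood; the five-design competition
(`~size`, `~ecotype`, `~size+ecotype`, `~size*ecotype`, `~1`) ranked by AICc
weights; parametric bootstrap of coefficients; pairwise ecotype contrasts of
means and scaling slopes with 95% percentile CIs; isometry/allometry
verdicts from the CI sign pattern (the traits are dimensionless, so a zero
slope is the isometric expectation); and a phylogenetic paired t-test for
humerus-vs-femur contrasts.

**Synthetic data** (`limbmorph.synthetic`) — voxel bones built from a hollow
elliptical frustum with flared solid caps (closed-form midshaft CSA and
second moments for oracle tests), corresponding landmarks on a fixed
parametric surface grid, pure-birth ultrametric phylogenies, clade-clustered
ecotype painting, Brownian ln-size, traits with λ-structured residuals, and
shapes built from ecotype means + an allometric vector + Brownian deviation.

**Pipeline** (`limbmorph.pipeline`, CLI `limbmorph`) — end-to-end
orchestration with stage-scoped random substreams: identical seeds give
byte-identical report tables.

## Worked example

Simulate a 76-species study (4 clade-clustered ecotypes), run the five-model
PGLS competition for cross-sectional shape, and classify its allometry:

```python
import limbmorph as lm
from limbmorph.synthetic import EvolParams, simulate_dataset
from limbmorph.phylo import slope_ci

ds = simulate_dataset(EvolParams(n_tips=76, seed=7))
comp = lm.fit_model_set(ds.traits["CSS"], ds.traits["lnsize"],
                        ds.traits["ecotype"], ds.phylogeny)
print(comp.table.round(3).to_string(index=False))

ens = lm.bootstrap_coefficients(comp.fits["size*ecotype"], n_boot=1000, seed=1)
call = slope_ci(ens)
print(f"across-ecotype CSS slope: {call.slope:.3f} "
      f"[{call.ci_low:.3f}:{call.ci_high:.3f}] -> {call.verdict}")
```

prints

```
       model    r2  lambda    aicc  delta_aic  aicw  supported
     ecotype 0.893   0.000 -30.960      0.000 0.705       True
size+ecotype 0.893   0.000 -28.886      2.074 0.250      False
size*ecotype 0.899   0.000 -25.479      5.481 0.045      False
        size 0.039   0.854  58.779     89.739 0.000      False
        null 0.000   0.864  59.507     90.467 0.000      False
across-ecotype CSS slope: 0.261 [-0.317:0.826] -> isometric
```

Read: ecotype alone is the best-supported predictor of this simulated CSS
trait (AICc weight 0.705; models within ΔAIC < 2 are flagged `supported`),
the residual phylogenetic signal collapses to λ = 0 once ecotype is in the
model, and the across-ecotype scaling slope's bootstrap CI straddles zero —
isometry. A CVA with jackknife cross-validation on the same dataset's
GPA-aligned shapes reclassifies species into their ecotype with 100.0%
accuracy (the generator's ecotype mean shapes are well separated).

The same analyses run from the shell:

```sh
limbmorph simulate --seed 7 --n-tips 76 --out data/
limbmorph fit --traits data/traits.csv --tree data/tree.nwk \
          --trait CSS --nboot 1000 --seed 1 --out results/
limbmorph run --seed 7 --out report/     # full pipeline, all stages
```

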