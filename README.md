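# readsem

Two-stage meta-analytic structural equation modeling (meta-SEM / TSSEM) of
the relations between broad cognitive abilities and reading skills.

Psychoeducational test batteries publish subtest-level correlation matrices
in their technical manuals. Pooled across batteries and samples, those
correlations let one ask how the Cattell–Horn–Carroll (CHC) broad
abilities — Gc, Gf, Gv, Ga, Gl, Gr, Gwm, Gs — relate to five narrow reading
skills: Phonological Decoding (PD), Lexical Decoding (LD), Decoding Speed
(DS), Reading Fluency (RF) and Reading Comprehension (RC). `readsem`
implements the full pipeline for analysts working with such a
correlation database:

1. **Stage 1 — meta-analytic pooling.** Each construct pair's correlations
   are Fisher-transformed (`z = artanh r`, sampling variance `1/(N−3)`)
   and pooled with a three-level random-effects model

   `z_ij = μ + u_j + e_ij + ε_ij`,  `u_j ~ N(0, τ²_between)`,
   `e_ij ~ N(0, τ²_within)`, `ε_ij ~ N(0, v_ij)`,

   where `j` indexes correlation matrices (correlations from the same
   matrix share examinees). μ and the variance components are estimated by
   REML; Cochran's Q and `I² = max(0, (Q−df)/Q)` summarize heterogeneity.
   The pooled correlations are assembled into a 13×13 matrix with unit
   diagonal, with the median of per-pair total sample sizes as the
   effective N.

2. **Stage 2 — structural model.** A latent general factor g loads on the
   eight broad abilities; the broad abilities predict all five reading
   skills; and the reading skills form a developmental cascade
   (PD → LD → DS → RF → RC, all forward edges). The model is estimated by
   normal-theory maximum likelihood in RAM notation
   (`Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`), with χ², CFI, TLI, RMSEA, SRMR, and
   likelihood-ratio comparison of the variant without Gv → reading paths
   (Δdf = 5). Every standardized effect is decomposed exactly into direct
   and indirect parts via `T = (I−B)⁻¹ − I`, with per-outcome R² and
   Keith's interpretive bands (<0.05 negligible, 0.05–0.09 small,
   0.10–0.24 moderate, >0.24 large).

Because real subtest-correlation databases are typically proprietary, the
package ships a synthetic-data generator (`readsem.synth`) that emulates
their statistical structure — clustered correlations, per-matrix N from 18
to 2901, incomplete construct coverage, between/within-matrix
heterogeneity on the z scale — so the whole pipeline is validated by
parameter recovery against known generating values.

## Worked example

```python
import numpy as np
from readsem import synth, consensus

cfg = synth.SynthConfig(n_matrices=300, seed=11)
db, truth = synth.simulate_database(cfg)
mm, fit, table = synth.run_pipeline(db, seed=1)

print(len(db), "records,", len(db.matrices), "matrices")
print("overall N (median rule):", mm.overall_N)
print("pooled r(Gc,Gf): %.3f  (generating value %.3f)"
      % (mm.R[0, 1], truth.population_r(("Gc", "Gf"))))
print("g-loading on Gc: %.3f" % fit.loadings["Gc"])
print("R2 for reading comprehension: %.2f" % table.r2["RC"])
```

prints

```
27153 records, 300 matrices
overall N (median rule): 37236
pooled r(Gc,Gf): 0.448  (generating value 0.448)
g-loading on Gc: 0.684
R2 for reading comprehension: 0.54
```

The pooled Gc–Gf correlation lands on the generating value λ_Gc·λ_Gf =
0.448, the fitted loading sits within one replicate's sampling error of
the generating 0.70, and the R² row reproduces the reference
decomposition.

The same pipeline is available from the shell:

```sh
readsem simulate --n-matrices 300 --seed 11 -o db/
readsem pool --records db/records.csv --classifications db/classifications.csv \
             --matrices db/matrices.csv -o pooled/
readsem sem --matrix pooled/pooled_matrix.csv --n 1764 --compare -o fit/
readsem report --fit fit/fit.json
```

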