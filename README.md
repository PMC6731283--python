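# degas

Decomposition of genetic associations: truncated singular value
decomposition (TSVD) of a phenome × genome GWAS summary-statistic matrix,
with a scoring system for interpreting the latent components, regulatory-
domain region enrichment of the driving variants, and a synthetic-data
generator so the whole pipeline is testable without access-controlled
biobank data.

## The problem and the method

Population-scale biobanks yield GWAS summary statistics for thousands of
phenotypes over hundreds of thousands of variants. Individual
phenotype–variant associations are hard to read jointly: pleiotropy means
the same variants drive many traits through a smaller number of latent
programs. This package characterises those programs directly from summary
statistics.

Per-phenotype association tables (PLINK2 `.glm.linear` / `.glm.logistic`
dialect) are filtered — variant QC (missingness < 1%, MAF > 0.01%,
Hardy–Weinberg p > 1e-7, LD-pruned set, MHC chr6:25477797–36448354
excluded), consequence subsets (all / coding / protein-truncating), and a
value filter (p < 0.001; SE < 0.08 for quantitative traits on the BETA
scale, SE < 0.2 for binary traits on the log-OR scale) — and the surviving
Wald Z-scores (estimate/SE) are assembled into an N×M matrix **W**, with
each phenotype row standardised to zero mean and unit variance. TSVD
factorises

```
W ≈ U S Vᵀ,    U: N×K phenotype singular vectors,
               S: K singular values,
               V: M×K variant singular vectors.
```

The k-th component explains `s_k² / ‖W‖²_F` of the variance; the number of
informative components is judged against a null expectation computed from
the rank of W, capped at K = 100.

The scoring system interprets the components:

- **factor scores** `F_p = US`, `F_v = VS` — phenotype and variant
  principal components;
- **contribution scores** `cntr_k(i) = u_{i,k}²` (and `v_{j,k}²`) — how
  much each phenotype or variant drives component k; each component's
  scores sum to one. Gene-level contributions sum variant contributions
  over gene buckets (variants sharing several genes form an intersection
  bucket; non-coding variants are their own buckets), conserving mass;
- **squared cosine scores** `cos²_i(k) = f_{i,k}² / Σ_{k'} f_{i,k'}²` —
  how much each component matters for one phenotype or variant; each
  entity's scores sum to one.

For biological characterisation, the top 5,000 variants of a component by
contribution score are exported as single-base regions and tested against
an ontology with a binomial regulatory-domain enrichment (a self-contained
kernel using basal-plus-extension gene domains): fold = hits/(n·π) and an
upper-tail binomial p-value, with table (p < 5e-6) and plot (p < 5e-7,
fold ≥ 2) significance filters. Specificity of enrichments across
components is summarised by the median pairwise Jaccard index of the gene
sets behind each component's top five enriched terms.

## Worked example

```python
import degas
from degas import scores as sc
from degas.simulate import simulate_latent_model, to_zmatrix, recovery_score

tables, phenotypes, truth = simulate_latent_model(
    n_phenotypes=200, n_variants=500, k0=3, s_profile=(10, 5, 1),
    noise_sd=0.1, seed=1,
)
w = to_zmatrix(tables, phenotypes)
est = degas.DeGAs(n_components=3, random_state=1).fit(w)
print("singular values:", est.singular_values_.round(3))
print(recovery_score(est.result_, truth))
```

prints

```
singular values: [10.     4.999  1.004]
  component   planted  abs_cosine
0       PC1  planted1    0.999982
1       PC2  planted2    0.999919
2       PC3  planted3    0.998125
```

The generator planted three latent components with singular values
(10, 5, 1) plus spectral-scale-0.1 noise; the fit recovers the singular
values to a fraction of a percent and matches each recovered variant
singular vector to its planted counterpart with |cosine| > 0.998.
Score tables then annotate the components:

```python
contrib = sc.phenotype_contribution(est.result_)
sc.top_drivers(contrib, "PC1", 3)
# [('PHE0092', 0.0529...), ('PHE0062', 0.0455...), ('PHE0009', 0.0405...)]

cosine = sc.squared_cosine(sc.factor_scores(est.result_), "phenotype")
sc.key_components(cosine, "PHE0001", 3)
#   component     score  cumulative
# 0       PC2  0.619367    0.619367
# 1       PC1  0.377162    0.996529
# 2       PC3  0.003471    1.000000
```

i.e. phenotype PHE0001's genetic associations are explained 62% by PC2 and
38% by PC1, while PC1 itself is driven most strongly by PHE0092.

The same pipeline runs from the shell:

```
degas simulate  --out-dir data --seed 1
degas decompose --in-dir data --out-dir run --k 10 --no-value-filter --seed 1
degas score     --run-dir run
degas report    --run-dir run
degas enrich    --run-dir run --in-dir data
```

(`--no-value-filter` because the generator emulates the significance
selection by masking entries itself; see `docs/methods.md`.)

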