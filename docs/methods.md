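# Methods

## Model

The package assumes a low-rank latent structure in the matrix of GWAS
association Z-scores. Let W be the N×M matrix whose entry (i, j) is the
Wald Z-score (effect estimate divided by its standard error) of variant j
on phenotype i, zero where no association survives filtering, with each
phenotype row standardised to zero mean and unit variance. Truncated SVD
gives W ≈ U S Vᵀ with K components; the k-th component explains
s_k²/‖W‖²_F of the total variance. All downstream scores are deterministic
functions of (U, S, V):

- factor scores F_p = US, F_v = VS (the phenotype and variant principal
  components; column k of each has norm s_k);
- contribution scores u_{i,k}² and v_{j,k}² (columns sum to one by
  orthonormality of U and V); gene contributions sum variant contributions
  over a partition of the variant axis;
- squared cosine scores f_{i,k}²/Σ_{k'} f_{i,k'}² (rows sum to one).

The two score families are complementary and deliberately not inverse to
each other: the top component of a phenotype need not list that phenotype
as its top driver (`tests/test_scores.py` asserts this on a constructed
counterexample).

### Z-score and fill conventions

The Z-score is estimate/SE (the standard Wald statistic); a signed Z
reconstructed from the p-value would be redundant with it. Entries with no
surviving association are encoded as exact zeros before standardisation —
the matrix is built only from records that pass all filters, and zero-fill
is the convention compatible with a dense factorisation. Phenotypes or
variants with no surviving records are dropped from the axes, so the
coding-only and PTV-only matrices are smaller than the all-variants one.

### Standardisation

Row standardisation uses the population (1/M) variance. Constant rows have
no defined transform and are dropped with a warning rather than imputed.

### Filters

Defaults equal the published analysis settings: variant QC keeps
missingness < 1%, MAF > 0.01%, HWE p > 1e-7, membership in the LD-pruned
set (consumed as an input flag; pruning itself is out of scope) and
position outside the MHC (chr6:25477797–36448354, 1-based inclusive; BED
exports are converted to 0-based half-open). The value filter keeps
p < 0.001 and SE < 0.08 (quantitative) or < 0.2 (binary). All thresholds
are strict inequalities and overridable per run. Filters commute; the
tests assert order invariance of their composition. Duplicate
(phenotype, variant) records are an error, not a silent overwrite.

### Component-count selection

The null expectation for per-component variance explained is implemented
as 1/Rank(W)², with the flat-spectrum alternative 1/Rank(W) (each of the
rank components explaining an equal share) available via the
`uniform=True` switch; the informative-component count is the largest k
whose observed fraction beats the null, capped at K = 100. K = 100 is the
default for the same efficiency reason a practitioner would use.

### Sign convention

SVD signs are arbitrary per component, so each component is canonicalised:
the largest-magnitude entry of its phenotype singular vector is made
positive and the flip mirrored in V, leaving U S Vᵀ unchanged. The
operation is idempotent and applied in every fit, making score tables and
plot frames reproducible. Contribution and squared-cosine scores are
themselves invariant to simultaneous sign flips.

### Solver

Dense LAPACK SVD is used when K is close to full rank or the matrix is
small (min dimension ≤ 100); otherwise ARPACK's implicitly restarted
Lanczos iteration (`scipy.sparse.linalg.svds`) with a start vector drawn
from the run's seed. Tests require agreement of the two routes to 1e-8.
Per-vector subspace comparisons are only meaningful for non-degenerate
spectra; tests use random matrices, where ties have probability zero, and
subspace-level checks elsewhere.

## Regulatory-domain enrichment

Region enrichment is a self-contained binomial regulatory-domain kernel.
Each gene gets a basal domain around its TSS (5 kb
upstream, 1 kb downstream, oriented by strand) extended on each side up to
1 Mb measured from the TSS, stopping early at a neighbouring gene's basal
domain and clipped to chromosome bounds; the basal domain is always
contained in the gene's own domain. For a term annotated to a gene set,
π is the fraction of the genome covered by the union of those genes'
domains, and with n submitted regions and `hits` of them inside the
covered set, p = Pr[Binomial(n, π) ≥ hits] and fold = hits/(n·π).
Submitted regions are single-base intervals at variant positions (top
5,000 variants per component by contribution score, ties broken by
variant id). Result tables keep p < 5e-6 (Bonferroni scale for a ~10⁴-term
ontology); plot output additionally requires p < 5e-7 and fold ≥ 2.
A complementary gene-based hypergeometric test is not implemented. Ontologies are consumed as flat (term, gene) tables;
hierarchical propagation and removal of obsolete terms are assumed done
upstream.

Specificity across components: for each component the top five enriched
terms by fold are collapsed to their gene union; the median pairwise
Jaccard index among the first k components is reported as a function of k.
Components with no enriched terms are skipped and logged.

## Synthetic data

The generator emulates exactly what the pipeline consumes: per-phenotype
association tables with a planted low-rank Z-score structure
W₀ = U₀S₀V₀ᵀ + ε, plus variant annotations, phenotype metadata, TSS
tables, chromosome sizes and ontologies.

- **Noise scale.** `noise_sd` is expressed on the spectral scale of the
  planted components: ε has i.i.d. Gaussian entries with standard
  deviation `noise_sd/(√N+√M)`, so the noise matrix's largest singular
  value is ≈ `noise_sd` and directly comparable to `s_profile`. This makes
  the default conditions (N=200, M=500, s=(10,5,1), noise_sd=0.1) a regime
  where all three components are recoverable, while noise_sd=2 buries the
  weakest component — the recovery-vs-noise monotonicity check spans both
  regimes. Noise is i.i.d. Gaussian; heavier-tailed options are deferred.
- **Value-filter emulation.** Planted Z-scores live far below genome-wide
  significance scale, so the p < 0.001 selection is emulated by the
  generator masking the weakest (1−sparsity) fraction of entries by |Z|,
  rather than by re-applying the value filter downstream; pipeline runs on
  generated data therefore pass `--no-value-filter` (SE values are drawn
  below the value-filter caps, so the SE rule is compatible either way).
- **Record conversion.** Each retained Z becomes an (estimate, SE, p)
  triple with SE drawn uniformly below the per-kind cap, estimate = Z·SE,
  and the two-sided normal-tail p; binary phenotypes are written as OR
  columns and log-transformed on ingest. Text serialisation uses %.17g so
  round-trips are bit-exact.
- **Annotations.** Planted counts are exact: each QC-failing variant
  violates exactly one rule, MHC variants sit inside the excluded window
  on a gene-free chr6, and consequence classes (PTV / coding / non-coding,
  including multi-gene intersection annotations) are planted among the
  QC-passing variants. Genes are spaced 1 Mb apart on chromosomes 1–5
  whose lengths make the union of regulatory domains tile them completely;
  a random term's domain coverage then equals its gene fraction, which
  keeps the binomial null calibrated (an early layout with sparse gene
  coverage made every term look enriched, because coding variants sit at
  TSSs while π stayed small).
- **Planted enrichment.** `simulate_enrichment_fixture` concentrates a
  chosen fraction of the leading component's variant-loading mass on the
  coding variants of a few target genes (drawn from the variant-richest
  genes so the support is sizeable) and plants an ontology term annotated
  to exactly those genes. At concentration 1.0 the term attains the top
  binomial fold and clears the table threshold across seeds; at the
  background rate it does not.

What the generator does **not** emulate: linkage disequilibrium between
variants, genotype-level sampling noise, heavy-tailed effect-size
distributions, correlated phenotypes beyond the planted factors, and
realistic GWAS p-value scales. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not the biological findings
obtainable from real biobank data.

## Problem sizes and determinism

Tests and the acceptance script run at N≈100–200 phenotypes and M≈500
variants with K₀ ≤ 3 planted components, 20–40-term ontologies and
≤ 100-region enrichment queries — sizes at which the dense SVD oracle is
exact and every run completes in seconds while exercising every code
path. Every source of randomness flows from an explicit integer seed;
identical configuration and seed reproduce all outputs byte-for-byte
(asserted end-to-end), and every output table carries the tool version and
a hash of the resolved configuration.

## Known limitations

- The individual-level phenotype-matrix decomposition uses median
  imputation, which biases towards the centre for strongly skewed
  phenotypes.
- Squared-cosine denominators sum over the K computed components, so the
  scores are relative to the truncated basis, not the full spectrum.
- The enrichment kernel supports no curated regulatory-domain exceptions
  (only the basal-plus-extension rule) and treats regions as independent,
  which is anti-conservative for correlated variants (LD is out of scope).
- `select_component_count` with the printed 1/Rank² null is permissive;
  the uniform 1/Rank alternative is stricter and available behind the
  config switch.
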