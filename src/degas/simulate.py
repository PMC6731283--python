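"""Synthetic GWAS summary-statistic datasets with planted low-rank structure.

The generator emulates the latent-component model the decomposition
assumes: a phenotype x variant Z-score matrix W0 = U S V^T + noise with
known orthonormal factors, converted back to per-phenotype association
tables (Z -> estimate/SE pairs with the p-value from the normal tail).
The significance-based value selection of real pipelines is emulated by
masking the weakest entries rather than simulating full GWAS.  Companion
generators emit variant annotations exercising every QC-filter branch and
gene-intersection rule, and ontologies with a planted enriched term, so
every pipeline stage is testable without any biobank access.

``noise_sd`` is expressed on the spectral scale of the planted components:
the noise matrix is drawn i.i.d. Gaussian with per-entry standard
deviation ``noise_sd / (sqrt(N) + sqrt(M))``, so its largest singular
value is approximately ``noise_sd`` and directly comparable to
``s_profile``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult, canonicalize_signs
from .sumstats import (
    MHC_REGION,
    AssociationRecord,
    PhenotypeRecord,
    VariantRecord,
    ZMatrix,
    build_zscore_matrix,
)

__all__ = [
    "SyntheticTruth",
    "simulate_latent_model",
    "simulate_annotations",
    "simulate_ontology",
    "simulate_enrichment_fixture",
    "recovery_score",
    "dataset_records",
    "to_zmatrix",
    "write_dataset",
    "write_annotations",
    "write_ontology",
]

#: Gene spacing on the synthetic chromosomes (bp).
GENE_SPACING = 1_000_000
#: Synthetic chr6 length; long enough to contain the MHC interval.
CHR6_SIZE = 37_000_000


@dataclass
class SyntheticTruth:
    """Planted factors and generator settings, serialised beside each dataset."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    noise_sd: float
    sparsity: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "U": self.U.tolist(),
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "noise_sd": self.noise_sd,
            "sparsity": self.sparsity,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            U=np.array(d["U"]),
            S=np.array(d["S"]),
            V=np.array(d["V"]),
            noise_sd=d["noise_sd"],
            sparsity=d["sparsity"],
            seed=d["seed"],
        )


def _orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def simulate_latent_model(
    n_phenotypes: int = 200,
    n_variants: int = 500,
    k0: int = 3,
    s_profile: Sequence[float] = (10.0, 5.0, 1.0),
    noise_sd: float = 0.1,
    sparsity: float = 1.0,
    seed: int = 0,
) -> tuple[dict, list, SyntheticTruth]:
    """Generate per-phenotype association tables with planted structure.

    Returns ``(tables, phenotypes, truth)`` where ``tables`` maps each
    phenotype id to a PLINK2-style association DataFrame, ``phenotypes``
    is the metadata (alternating quantitative/binary kinds), and ``truth``
    carries the planted factors.  A ``1 - sparsity`` fraction of entries
    (the weakest by |Z|) is masked from the emitted tables, emulating the
    significance-based value selection.  Fully reproducible from ``seed``.
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    if k0 > min(n_phenotypes, n_variants) or k0 < 0:
        raise ValueError("k0 must be in [0, min(n_phenotypes, n_variants)]")
    s = np.asarray(s_profile, dtype=float)
    if len(s) != k0 or (k0 and (np.any(s <= 0) or np.any(np.diff(s) > 0))):
        raise ValueError("s_profile must be positive, non-increasing, of length k0")

    rng = np.random.default_rng(seed)
    U = _orthonormal(rng, n_phenotypes, k0) if k0 else np.zeros((n_phenotypes, 0))
    V = _orthonormal(rng, n_variants, k0) if k0 else np.zeros((n_variants, 0))
    U, V = canonicalize_signs(U, V)
    W0 = (U * s) @ V.T
    if noise_sd > 0:
        scale = noise_sd / (math.sqrt(n_phenotypes) + math.sqrt(n_variants))
        W0 = W0 + scale * rng.standard_normal((n_phenotypes, n_variants))

    mask = np.ones_like(W0, dtype=bool)
    if sparsity < 1:
        n_keep = int(round(sparsity * W0.size))
        order = np.argsort(-np.abs(W0), axis=None, kind="stable")
        mask = np.zeros(W0.size, dtype=bool)
        mask[order[:n_keep]] = True
        mask = mask.reshape(W0.shape)

    phen_ids = [f"PHE{i + 1:04d}" for i in range(n_phenotypes)]
    var_ids = [f"VAR{j + 1:05d}" for j in range(n_variants)]
    phenotypes = [
        PhenotypeRecord(
            phenotype_id=pid,
            kind="quantitative" if i % 2 == 0 else "binary",
            n_effective=int(rng.integers(1000, 10000)),
            group=f"group{'ABC'[i % 3]}",
        )
        for i, pid in enumerate(phen_ids)
    ]

    tables = {}
    for i, (pid, phen) in enumerate(zip(phen_ids, phenotypes)):
        keep = np.flatnonzero(mask[i])
        z = W0[i, keep]
        if phen.kind == "quantitative":
            se = rng.uniform(0.02, 0.075, size=len(keep))
        else:
            se = rng.uniform(0.05, 0.19, size=len(keep))
        est = z * se
        p = 2.0 * stats.norm.sf(np.abs(z))
        df = pd.DataFrame({"ID": [var_ids[j] for j in keep]})
        if phen.kind == "quantitative":
            df["BETA"] = est
        else:
            df["OR"] = np.exp(est)
        df["SE"] = se
        df["P"] = p
        tables[pid] = df

    truth = SyntheticTruth(U=U, S=s, V=V, noise_sd=noise_sd, sparsity=sparsity, seed=seed)
    return tables, phenotypes, truth


def dataset_records(
    tables: Mapping[str, pd.DataFrame], phenotypes: Sequence[PhenotypeRecord]
) -> list[AssociationRecord]:
    """Convert generated tables to association records without file round-trips."""
    kinds = {p.phenotype_id: p.kind for p in phenotypes}
    records = []
    for pid, df in tables.items():
        est_col = "BETA" if kinds[pid] == "quantitative" else "OR"
        for row in df.itertuples(index=False):
            e = getattr(row, est_col)
            if est_col == "OR":
                e = math.log(e)
            records.append(AssociationRecord(pid, str(row.ID), float(e), float(row.SE), float(row.P)))
    return records


def to_zmatrix(
    tables: Mapping[str, pd.DataFrame], phenotypes: Sequence[PhenotypeRecord]
) -> ZMatrix:
    """Assemble the generated dataset straight into an unstandardised ZMatrix."""
    records = dataset_records(tables, phenotypes)
    phen_ids = [p.phenotype_id for p in phenotypes]
    var_ids = sorted({r.variant_id for r in records})
    return build_zscore_matrix(records, phen_ids, var_ids)


def write_dataset(out_dir, tables, phenotypes, truth: SyntheticTruth) -> None:
    """Write association tables, phenotype metadata and the truth sidecar."""
    out_dir = Path(out_dir)
    (out_dir / "sumstats").mkdir(parents=True, exist_ok=True)
    kinds = {p.phenotype_id: p.kind for p in phenotypes}
    for pid in sorted(tables):
        tables[pid].to_csv(
            out_dir / "sumstats" / f"{pid}.glm.tsv",
            sep="\t",
            index=False,
            float_format="%.17g",
        )
    meta = pd.DataFrame(
        {
            "ID": [p.phenotype_id for p in phenotypes],
            "KIND": [p.kind for p in phenotypes],
            "N_EFFECTIVE": [p.n_effective for p in phenotypes],
            "GROUP": [p.group for p in phenotypes],
        }
    )
    meta.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
    truth.to_json(out_dir / "truth.json")
    _ = kinds  # kinds embedded in metadata file


# ---------------------------------------------------------------------------
# Annotations


def simulate_annotations(
    n_variants: int = 500,
    gene_count: int = 40,
    ptv_fraction: float = 0.1,
    coding_fraction: float = 0.3,
    shared_gene_fraction: float = 0.05,
    mhc_fraction: float = 0.05,
    seed: int = 0,
    fail_missingness_fraction: float = 0.0,
    fail_maf_fraction: float = 0.0,
    fail_hwe_fraction: float = 0.0,
    fail_ld_fraction: float = 0.0,
) -> tuple[list[VariantRecord], pd.DataFrame, dict, dict]:
    """Variant annotations plus a TSS table exercising every filter branch.

    Returns ``(variants, tss_table, chrom_sizes, counts)``.  Exact planted
    counts per class (MHC placement, each QC failure mode, consequence
    classes, multi-gene annotations) are in the ``counts`` truth sidecar.
    Each QC-failing variant violates exactly one rule.  Consequence
    fractions are taken of the total variant count but planted among the
    QC-passing variants; coding variants are positioned inside their gene's
    basal window so region enrichment can recover gene-level signal.

    Genes are spaced :data:`GENE_SPACING` apart on chromosomes 1-5, whose
    lengths are chosen so the union of regulatory domains tiles them
    completely; a random ontology term's domain coverage then matches its
    gene fraction and the binomial enrichment null is calibrated.  chr6
    exists (gene-free) only when MHC variants are planted.
    """
    fracs = (ptv_fraction, coding_fraction, shared_gene_fraction, mhc_fraction,
             fail_missingness_fraction, fail_maf_fraction, fail_hwe_fraction,
             fail_ld_fraction)
    if any(f < 0 or f > 1 for f in fracs):
        raise ValueError("all fractions must lie in [0, 1]")
    if ptv_fraction + coding_fraction > 1:
        raise ValueError("consequence fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    n_mhc = round(mhc_fraction * n_variants)
    n_miss = round(fail_missingness_fraction * n_variants)
    n_maf = round(fail_maf_fraction * n_variants)
    n_hwe = round(fail_hwe_fraction * n_variants)
    n_ld = round(fail_ld_fraction * n_variants)
    n_fail = n_mhc + n_miss + n_maf + n_hwe + n_ld
    n_pass = n_variants - n_fail
    if n_pass < 0:
        raise ValueError("failure fractions exceed the variant count")
    n_ptv = min(round(ptv_fraction * n_variants), n_pass)
    n_cod = min(round(coding_fraction * n_variants), n_pass - n_ptv)

    # genes tile chromosomes 1-5 at GENE_SPACING; chrom length ends half a
    # spacing after the last TSS so 1 Mb extensions cover every base
    genes = [f"GENE{g + 1:04d}" for g in range(gene_count)]
    gene_chrom = [str(1 + g % 5) for g in range(gene_count)]
    gene_tss = [GENE_SPACING // 2 + (g // 5) * GENE_SPACING for g in range(gene_count)]
    gene_strand = ["+" if g % 2 == 0 else "-" for g in range(gene_count)]
    tss_table = pd.DataFrame(
        {"gene": genes, "chrom": gene_chrom, "tss": gene_tss, "strand": gene_strand}
    )
    chrom_sizes = {}
    for c in range(1, 6):
        n_on_chrom = sum(1 for gc in gene_chrom if gc == str(c))
        chrom_sizes[str(c)] = max(1, n_on_chrom) * GENE_SPACING
    if n_mhc > 0:
        chrom_sizes["6"] = CHR6_SIZE

    mhc_chrom, mhc_lo, mhc_hi = MHC_REGION

    def _passing_qc():
        return dict(maf=float(rng.uniform(0.01, 0.5)), missingness=float(rng.uniform(0, 0.009)),
                    hwe_p=float(rng.uniform(0.01, 1.0)), ld_pruned_in=True)

    variants: list[VariantRecord] = []
    counts = {"mhc": n_mhc, "missingness": n_miss, "maf": n_maf, "hwe": n_hwe,
              "ld_pruned": n_ld, "ptv": n_ptv, "coding_nonptv": n_cod,
              "noncoding": n_variants - n_ptv - n_cod, "multi_gene": 0}
    idx = 0

    def _vid():
        nonlocal idx
        idx += 1
        return f"VAR{idx:05d}"

    for _ in range(n_mhc):
        variants.append(VariantRecord(
            _vid(), mhc_chrom, int(rng.integers(mhc_lo, mhc_hi + 1)),
            "noncoding", frozenset(), **_passing_qc()))
    for fail, n_f in (("missingness", n_miss), ("maf", n_maf), ("hwe", n_hwe), ("ld", n_ld)):
        for _ in range(n_f):
            qc = _passing_qc()
            if fail == "missingness":
                qc["missingness"] = float(rng.uniform(0.011, 0.05))
            elif fail == "maf":
                qc["maf"] = float(rng.uniform(1e-6, 9e-5))
            elif fail == "hwe":
                qc["hwe_p"] = float(rng.uniform(1e-10, 9e-8))
            else:
                qc["ld_pruned_in"] = False
            chrom = str(rng.integers(1, 6))
            variants.append(VariantRecord(
                _vid(), chrom, int(rng.integers(1, chrom_sizes[chrom])),
                "noncoding", frozenset(), **qc))

    # QC-passing variants: PTV, then coding non-PTV, then non-coding
    n_shared = min(round(shared_gene_fraction * n_variants), n_ptv + n_cod)
    coding_slots = n_ptv + n_cod
    shared_slots = set(rng.choice(coding_slots, size=n_shared, replace=False)) if n_shared else set()
    counts["multi_gene"] = n_shared
    for slot in range(coding_slots):
        g = int(rng.integers(0, gene_count))
        if slot in shared_slots and gene_count > 1:
            g2 = (g + 1) % gene_count
            gene_set = frozenset({genes[g], genes[g2]})
        else:
            gene_set = frozenset({genes[g]})
        pos = gene_tss[g] + int(rng.integers(-400, 401))
        cons = "ptv" if slot < n_ptv else "coding_nonptv"
        variants.append(VariantRecord(
            _vid(), gene_chrom[g], pos, cons, gene_set, **_passing_qc()))
    for _ in range(n_pass - coding_slots):
        chrom = str(rng.integers(1, 6))
        variants.append(VariantRecord(
            _vid(), chrom, int(rng.integers(1, chrom_sizes[chrom])),
            "noncoding", frozenset(), **_passing_qc()))

    return variants, tss_table, chrom_sizes, counts


def write_annotations(out_dir, variants: Sequence[VariantRecord], tss_table: pd.DataFrame,
                      chrom_sizes: Mapping[str, int]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "ID": [v.variant_id for v in variants],
            "CHROM": [v.chrom for v in variants],
            "POS": [v.pos for v in variants],
            "CONSEQUENCE": [v.consequence for v in variants],
            "GENES": [",".join(sorted(v.genes)) for v in variants],
            "MAF": [v.maf for v in variants],
            "MISSINGNESS": [v.missingness for v in variants],
            "HWE_P": [v.hwe_p for v in variants],
            "LD_PRUNED": [int(v.ld_pruned_in) for v in variants],
        }
    )
    df.to_csv(out_dir / "variants.tsv", sep="\t", index=False, float_format="%.17g")
    tss_table.to_csv(out_dir / "tss.tsv", sep="\t", index=False)
    with open(out_dir / "chrom.sizes", "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"chr{chrom}\t{chrom_sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# Ontology


def simulate_ontology(
    genes: Sequence[str],
    n_terms: int = 20,
    planted: tuple | None = None,
    seed: int = 0,
    component_top_genes: Mapping[str, Sequence[str]] | None = None,
    genes_per_term: int = 8,
) -> dict[str, set]:
    """Ontology term -> gene-set table with an optionally planted enrichment.

    ``planted = (component, term_id, concentration)`` makes the named term's
    gene set draw a ``concentration`` fraction of its genes from the top
    contributing genes of that component (supplied via
    ``component_top_genes``), the rest at random, so region enrichment
    should recover the term when concentration is high.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: dict[str, set] = {}
    for t in range(n_terms):
        size = min(genes_per_term, len(genes))
        terms[f"TERM{t + 1:04d}"] = set(rng.choice(genes, size=size, replace=False))
    if planted is not None:
        component, term_id, concentration = planted
        if not (0 <= concentration <= 1):
            raise ValueError("concentration must lie in [0, 1]")
        if component_top_genes is None:
            raise ValueError("planting a term requires component_top_genes")
        top = [g for g in component_top_genes[component] if g in set(genes)]
        n_top = min(int(round(concentration * genes_per_term)), len(top))
        rest_pool = [g for g in genes if g not in top[:n_top]]
        n_rest = min(genes_per_term - n_top, len(rest_pool))
        planted_set = set(top[:n_top]) | set(rng.choice(rest_pool, size=n_rest, replace=False))
        terms[term_id] = planted_set
    return terms


def write_ontology(path, terms: Mapping[str, set]) -> None:
    with open(path, "w") as fh:
        fh.write("term\tgene\n")
        for t in sorted(terms):
            for g in sorted(terms[t]):
                fh.write(f"{t}\t{g}\n")


def simulate_enrichment_fixture(
    n_phenotypes: int = 100,
    n_variants: int = 500,
    n_terms: int = 20,
    n_target_genes: int = 5,
    concentration: float = 1.0,
    seed: int = 0,
):
    """End-to-end fixture with a planted regulatory-domain enrichment.

    Picks ``n_target_genes`` genes, concentrates a ``concentration``
    fraction of the leading component's variant-loading mass on the coding
    variants of those genes, and plants an ontology term (``TERM0001``)
    annotated to exactly those genes.  At high concentration the term
    should attain the top binomial fold for that component; at the
    background rate (concentration ~ support size / M) it should not be
    significant.

    Returns a dict with the association tables, phenotypes, truth, variant
    annotations, TSS table, chromosome sizes, ontology terms, target genes
    and the planted term id.
    """
    if not (0 <= concentration <= 1):
        raise ValueError("concentration must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    variants, tss, chrom_sizes, counts = simulate_annotations(
        n_variants, mhc_fraction=0.0, seed=seed
    )
    genes = list(tss["gene"])
    # target genes drawn from the variant-richest genes, so the planted
    # term's domains genuinely host a sizeable block of variants
    host_counts: dict = {}
    for v in variants:
        for g in v.genes:
            host_counts[g] = host_counts.get(g, 0) + 1
    ranked = sorted(genes, key=lambda g: (-host_counts.get(g, 0), g))
    pool = ranked[: max(2 * n_target_genes, 10)]
    target = set(rng.choice(pool, size=n_target_genes, replace=False))
    support = np.array(
        [j for j, v in enumerate(variants) if v.genes & target], dtype=int
    )
    if len(support) == 0:
        raise ValueError("target genes host no variants; increase coding fractions")

    # leading variant singular vector: `concentration` of its squared mass
    # on the support, the rest spread over the remaining variants
    v1 = np.zeros(n_variants)
    signs = rng.choice([-1.0, 1.0], size=n_variants)
    v1[support] = math.sqrt(concentration / len(support))
    off = np.setdiff1d(np.arange(n_variants), support)
    if concentration < 1:
        v1[off] = math.sqrt((1 - concentration) / len(off))
    v1 *= signs
    v1 /= np.linalg.norm(v1)
    v2 = rng.standard_normal(n_variants)
    v2 -= (v2 @ v1) * v1
    v2 /= np.linalg.norm(v2)
    V = np.column_stack([v1, v2])
    U = _orthonormal(rng, n_phenotypes, 2)
    U, V = canonicalize_signs(U, V)
    s = np.array([10.0, 5.0])
    scale = 0.1 / (math.sqrt(n_phenotypes) + math.sqrt(n_variants))
    W0 = (U * s) @ V.T + scale * rng.standard_normal((n_phenotypes, n_variants))

    phen_ids = [f"PHE{i + 1:04d}" for i in range(n_phenotypes)]
    var_ids = [v.variant_id for v in variants]
    phenotypes = [
        PhenotypeRecord(pid, "quantitative", 1000, "groupA") for pid in phen_ids
    ]
    tables = {}
    for i, pid in enumerate(phen_ids):
        se = rng.uniform(0.02, 0.075, size=n_variants)
        tables[pid] = pd.DataFrame(
            {
                "ID": var_ids,
                "BETA": W0[i] * se,
                "SE": se,
                "P": 2.0 * stats.norm.sf(np.abs(W0[i])),
            }
        )
    truth = SyntheticTruth(U=U, S=s, V=V, noise_sd=0.1, sparsity=1.0, seed=seed)

    term_id = "TERM0001"
    terms = simulate_ontology(
        genes,
        n_terms,
        planted=("PC1", term_id, 1.0),
        seed=seed,
        component_top_genes={"PC1": sorted(target)},
        genes_per_term=n_target_genes,
    )
    return {
        "tables": tables,
        "phenotypes": phenotypes,
        "truth": truth,
        "variants": variants,
        "tss": tss,
        "chrom_sizes": chrom_sizes,
        "terms": terms,
        "target_genes": target,
        "planted_term": term_id,
        "counts": counts,
    }


# ---------------------------------------------------------------------------
# Recovery metrics


def recovery_score(d: DecompositionResult, truth: SyntheticTruth) -> pd.DataFrame:
    """Match recovered to planted components and report absolute cosines.

    Greedy one-to-one matching on the absolute cosine between recovered and
    planted variant singular vectors; returns one row per matched pair
    (recovered component, planted component, |cosine|).
    """
    if d.V.shape[0] != truth.V.shape[0]:
        raise ValueError(
            f"variant axes differ: recovered {d.V.shape[0]} vs planted {truth.V.shape[0]}"
        )
    k0 = truth.V.shape[1]
    if k0 == 0:
        return pd.DataFrame(columns=["component", "planted", "abs_cosine"])
    C = np.abs(d.V.T @ truth.V)  # k_rec x k0
    rows = []
    used_r: set = set()
    used_p: set = set()
    for _ in range(min(d.k, k0)):
        best = -1.0
        best_rp = None
        for r in range(d.k):
            if r in used_r:
                continue
            for p in range(k0):
                if p in used_p:
                    continue
                if C[r, p] > best:
                    best, best_rp = C[r, p], (r, p)
        r, p = best_rp
        used_r.add(r)
        used_p.add(p)
        rows.append((f"PC{r + 1}", f"planted{p + 1}", float(best)))
    return pd.DataFrame(rows, columns=["component", "planted", "abs_cosine"])
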