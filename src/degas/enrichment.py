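"""Regulatory-domain enrichment of top-contributing variants and term-set
specificity.

For each latent component the top variants by contribution score are
exported as single-base regions and tested, term by term, with a binomial
region-based enrichment: a term's regulatory domains (basal window around
each annotated gene's TSS plus a bounded extension) cover a fraction pi of
the genome, the number of regions falling in that covered set is binomial
under the null, and enrichment is reported as fold = hits / (n * pi) with
an upper-tail binomial p-value.  Specificity of enrichments across
components is summarised by the Jaccard similarity of the gene sets behind
each component's top enriched terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scores import ScoreTable
from .sumstats import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryDomain",
    "EnrichmentResult",
    "select_top_variants",
    "variants_to_bed",
    "read_ontology_table",
    "read_chrom_sizes",
    "build_regulatory_domains",
    "binomial_region_enrichment",
    "filter_significant",
    "jaccard_similarity",
    "component_specificity_profile",
]

#: Bonferroni-corrected p threshold for result tables (9,554-term-scale ontology).
TABLE_P_THRESHOLD = 5e-6
#: Stricter display filter for plots: p < 5e-7 and fold >= 2.
PLOT_P_THRESHOLD = 5e-7
PLOT_FOLD_THRESHOLD = 2.0


@dataclass(frozen=True)
class RegulatoryDomain:
    """Genomic interval attributed to a gene (0-based half-open)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty domain for {self.gene}")


@dataclass(frozen=True)
class EnrichmentResult:
    component: str
    term_id: str
    fold: float
    p_value: float
    n_hits: int
    n_regions: int


def select_top_variants(
    t: ScoreTable, component: str | int, n: int = 5000
) -> list[str]:
    """Top-n variants of a component by contribution score (ties by id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(component, int):
        component = f"PC{component}"
    col = t.frame[component]
    order = sorted(col.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [str(v) for v, _ in order[:n]]


def variants_to_bed(
    variant_ids: Sequence[str],
    annotations: Mapping[str, VariantRecord],
    scores: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Single-base BED intervals (0-based half-open) for selected variants."""
    rows = []
    for vid in variant_ids:
        v = annotations[vid]
        score = float(scores[vid]) if scores is not None else 0.0
        rows.append((v.chrom, v.pos - 1, v.pos, vid, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def read_ontology_table(path) -> dict[str, set]:
    """Flat two-column (term, gene) TSV -> term -> gene set mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    term_col, gene_col = df.columns[:2]
    terms: dict[str, set] = {}
    for t, g in zip(df[term_col], df[gene_col]):
        terms.setdefault(str(t), set()).add(str(g))
    return terms


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC chrom.sizes file -> chrom -> length mapping."""
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split()[:2]
        sizes[chrom.removeprefix("chr")] = int(size)
    return sizes


def build_regulatory_domains(
    tss_table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Assign each gene a regulatory domain around its TSS.

    The basal domain spans ``basal_up`` bp upstream to ``basal_down`` bp
    downstream of the TSS, oriented by strand.  It is then extended up to
    ``extension`` bp from the TSS on each side, stopping early at a
    neighbouring gene's basal domain, and clipped to chromosome bounds.

    ``tss_table`` needs columns gene, chrom, tss, strand.
    """
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in tss_table.columns:
            raise ValueError(f"TSS table is missing column {col!r}")
    if tss_table["gene"].duplicated().any():
        dup = tss_table.loc[tss_table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene symbol in TSS table: {dup}")

    out: list[RegulatoryDomain] = []
    for chrom, sub in tss_table.groupby("chrom"):
        chrom = str(chrom).removeprefix("chr")
        size = chrom_sizes[chrom]
        sub = sub.sort_values("tss").reset_index(drop=True)
        basal = []
        for row in sub.itertuples(index=False):
            tss = int(row.tss)
            if row.strand == "+":
                lo, hi = tss - basal_up, tss + basal_down
            else:
                lo, hi = tss - basal_down, tss + basal_up
            basal.append((max(0, lo), min(size, hi)))
        for i, row in enumerate(sub.itertuples(index=False)):
            tss = int(row.tss)
            start = max(0, tss - extension, basal[i - 1][1] if i > 0 else 0)
            end = min(size, tss + extension) if i == len(sub) - 1 else min(
                size, tss + extension, basal[i + 1][0]
            )
            # the basal domain is always part of the gene's own domain
            start = min(start, basal[i][0])
            end = max(end, basal[i][1])
            out.append(RegulatoryDomain(str(row.gene), chrom, start, min(size, end)))
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _coverage_by_chrom(domains: Iterable[RegulatoryDomain]) -> dict[str, list]:
    by_chrom: dict[str, list] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    return {c: _merge_intervals(iv) for c, iv in by_chrom.items()}


def _covered_bp(cov: Mapping[str, list]) -> int:
    return sum(hi - lo for iv in cov.values() for lo, hi in iv)


def _region_hits(regions: pd.DataFrame, cov: Mapping[str, list]) -> int:
    hits = 0
    for chrom, sub in regions.groupby("chrom"):
        iv = cov.get(str(chrom).removeprefix("chr"))
        if not iv:
            continue
        starts = np.array([lo for lo, _ in iv])
        ends = np.array([hi for _, hi in iv])
        # single-base region [s, e): hit iff some interval [lo, hi) overlaps it
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        idx = np.searchsorted(starts, e, side="left") - 1
        ok = (idx >= 0) & (e > starts[np.clip(idx, 0, None)]) & (s < ends[np.clip(idx, 0, None)])
        hits += int(ok.sum())
    return hits


def binomial_region_enrichment(
    regions: pd.DataFrame,
    domains: Sequence[RegulatoryDomain],
    terms: Mapping[str, set],
    genome_size: int,
    component: str = "PC1",
) -> list[EnrichmentResult]:
    """Binomial region-based enrichment of each ontology term.

    For each term, pi is the fraction of the genome covered by the union of
    the regulatory domains of the term's genes; with n regions submitted and
    ``hits`` falling in the covered set, p = Pr[Binomial(n, pi) >= hits] and
    fold = hits / (n * pi).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = len(regions)
    by_gene: dict[str, list] = {}
    for d in domains:
        by_gene.setdefault(d.gene, []).append(d)

    results = []
    for term_id in sorted(terms):
        term_domains = [d for g in terms[term_id] for d in by_gene.get(g, [])]
        cov = _coverage_by_chrom(term_domains)
        pi = _covered_bp(cov) / genome_size
        hits = _region_hits(regions, cov)
        if pi == 0:
            if hits > 0:
                raise ValueError(
                    f"term {term_id}: {hits} hits but zero domain coverage"
                )
            fold, p = 0.0, 1.0
        elif hits == 0:
            fold, p = 0.0, 1.0
        else:
            fold = hits / (n * pi)
            p = float(stats.binom.sf(hits - 1, n, pi))
        results.append(EnrichmentResult(component, term_id, fold, p, hits, n))
    return results


def filter_significant(
    results: Iterable[EnrichmentResult], mode: str = "table"
) -> list[EnrichmentResult]:
    """Significance filters: table keeps p < 5e-6; plot keeps p < 5e-7 and fold >= 2."""
    if mode == "table":
        return [r for r in results if r.p_value < TABLE_P_THRESHOLD]
    if mode == "plot":
        return [
            r
            for r in results
            if r.p_value < PLOT_P_THRESHOLD and r.fold >= PLOT_FOLD_THRESHOLD
        ]
    raise ValueError(f"unknown filter mode {mode!r}; expected table|plot")


def _gene_union(term_ids: Iterable[str], terms: Mapping[str, set]) -> set:
    out: set = set()
    for t in term_ids:
        if t not in terms:
            raise KeyError(f"unknown ontology term {t!r}")
        out |= terms[t]
    return out


def jaccard_similarity(
    term_set_a: Iterable[str], term_set_b: Iterable[str], terms: Mapping[str, set]
) -> float:
    """Jaccard index between the gene unions of two term sets, in [0, 1]."""
    a = _gene_union(term_set_a, terms)
    b = _gene_union(term_set_b, terms)
    union = a | b
    if not union:
        logger.warning("both term sets have empty gene unions; similarity defined as 0")
        return 0.0
    return len(a & b) / len(union)


def top_terms_by_fold(
    results: Iterable[EnrichmentResult], n: int = 5
) -> list[str]:
    """Top-n enriched terms sorted by binomial fold (ties by p then term id)."""
    order = sorted(results, key=lambda r: (-r.fold, r.p_value, r.term_id))
    return [r.term_id for r in order[:n]]


def component_specificity_profile(
    enrichments: Mapping[str, Sequence[EnrichmentResult]],
    terms: Mapping[str, set],
    top_terms: int = 5,
    k_values: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Median pairwise Jaccard of top-term gene sets among the first k components.

    Components without any enriched term are skipped (and logged).  Returns
    a table with columns k, n_pairs, median_jaccard.
    """
    comp_terms: dict[str, list] = {}
    for comp in enrichments:
        tops = top_terms_by_fold(enrichments[comp], n=top_terms)
        if not tops:
            logger.warning("component %s has no enriched terms; skipped", comp)
            continue
        comp_terms[comp] = tops
    comps = list(comp_terms)
    if k_values is None:
        k_values = range(2, len(comps) + 1)
    rows = []
    for k in k_values:
        subset = comps[: min(k, len(comps))]
        sims = [
            jaccard_similarity(comp_terms[a], comp_terms[b], terms)
            for a, b in combinations(subset, 2)
        ]
        if sims:
            rows.append((k, len(sims), float(np.median(sims))))
    return pd.DataFrame(rows, columns=["k", "n_pairs", "median_jaccard"])
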