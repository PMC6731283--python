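"""Scoring system interpreting the latent components.

Factor scores F_p = U S and F_v = V S are the phenotype and variant
principal components.  Contribution scores (squared singular-vector
entries) quantify how much each phenotype / variant / gene drives a
component and sum to one per component; squared cosine scores (squared
factor scores normalised across components) quantify how much each
component matters for one entity and sum to one per entity.  The two are
complementary and do not have an inverse-mapping property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import DecompositionResult
from .sumstats import VariantRecord

__all__ = [
    "FactorScores",
    "ScoreTable",
    "GeneGroup",
    "factor_scores",
    "phenotype_contribution",
    "variant_contribution",
    "build_gene_groups",
    "gene_contribution",
    "squared_cosine",
    "top_drivers",
    "key_components",
    "group_contribution",
    "collapse_small_segments",
    "biplot_frame",
]


def _result(d) -> DecompositionResult:
    # accept either a DecompositionResult or a fitted DeGAs estimator
    return d.result_ if hasattr(d, "result_") else d


def _labels(ids, n, prefix) -> list:
    return list(ids) if ids else [f"{prefix}{i}" for i in range(n)]


@dataclass
class FactorScores:
    """Principal-component coordinates of phenotypes (U S) and variants (V S)."""

    phenotype: pd.DataFrame  # N x K
    variant: pd.DataFrame  # M x K


@dataclass
class ScoreTable:
    """Entity x component table of contribution or squared-cosine scores."""

    frame: pd.DataFrame
    axis: str  # phenotype | variant | gene | phenotype_group
    score_kind: str  # contribution | squared_cosine

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def write(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.frame.to_csv(fh, sep="\t", float_format="%.17g", index_label=self.axis)


@dataclass(frozen=True)
class GeneGroup:
    """A gene-contribution bucket: one gene, an intersection of genes sharing
    variants, or a per-variant pseudo-gene for non-coding variants."""

    key: frozenset
    member_variants: frozenset

    @property
    def label(self) -> str:
        return "&".join(sorted(self.key))


def factor_scores(d) -> FactorScores:
    """F_p = U S and F_v = V S; column k of each has Euclidean norm s_k."""
    d = _result(d)
    comp = d.component_labels()
    phen = _labels(d.phenotype_ids, d.U.shape[0], "phen")
    var = _labels(d.variant_ids, d.V.shape[0], "var")
    return FactorScores(
        phenotype=pd.DataFrame(d.U * d.S, index=phen, columns=comp),
        variant=pd.DataFrame(d.V * d.S, index=var, columns=comp),
    )


def phenotype_contribution(d) -> ScoreTable:
    """Phenotype contribution scores: cntr_k(i) = u_{i,k}^2."""
    d = _result(d)
    frame = pd.DataFrame(
        d.U**2,
        index=_labels(d.phenotype_ids, d.U.shape[0], "phen"),
        columns=d.component_labels(),
    )
    return ScoreTable(frame, "phenotype", "contribution")


def variant_contribution(d) -> ScoreTable:
    """Variant contribution scores: cntr_k(j) = v_{j,k}^2."""
    d = _result(d)
    frame = pd.DataFrame(
        d.V**2,
        index=_labels(d.variant_ids, d.V.shape[0], "var"),
        columns=d.component_labels(),
    )
    return ScoreTable(frame, "variant", "contribution")


def build_gene_groups(variants: Iterable[VariantRecord]) -> list[GeneGroup]:
    """Partition the variant axis into gene-contribution buckets.

    Variants with the same non-empty gene set share a bucket keyed by that
    set (so a variant annotated to two genes counts once, toward the
    intersection bucket, not once per gene); each non-coding variant with no
    gene forms its own singleton bucket keyed by its variant id.
    """
    buckets: dict = {}
    for v in variants:
        key = v.genes if v.genes else frozenset({v.variant_id})
        buckets.setdefault(key, set()).add(v.variant_id)
    return [
        GeneGroup(key=key, member_variants=frozenset(members))
        for key, members in sorted(buckets.items(), key=lambda kv: sorted(kv[0]))
    ]


def gene_contribution(d, groups: Sequence[GeneGroup]) -> ScoreTable:
    """Gene contribution: sum of variant contributions over each bucket.

    The groups must partition the variant axis, which guarantees the
    per-component column sums stay exactly one.
    """
    var = variant_contribution(d)
    covered: list = []
    for g in groups:
        covered.extend(g.member_variants)
    if len(covered) != len(set(covered)) or set(covered) != set(var.frame.index):
        raise ValueError("gene groups must partition the variant axis exactly")
    rows = {g.label: var.frame.loc[sorted(g.member_variants)].sum(axis=0) for g in groups}
    frame = pd.DataFrame(rows).T.loc[[g.label for g in groups]]
    return ScoreTable(frame, "gene", "contribution")


def squared_cosine(f: FactorScores, axis: str) -> ScoreTable:
    """Squared cosine scores: f_{i,k}^2 normalised across the K components.

    Rows sum to one relative to the truncated basis.  Entities whose factor
    scores are all zero have no direction in the latent space; their rows
    are excluded from the table rather than propagated as NaN.
    """
    if axis not in ("phenotype", "variant"):
        raise ValueError("axis must be 'phenotype' or 'variant'")
    frame = f.phenotype if axis == "phenotype" else f.variant
    sq = frame.to_numpy() ** 2
    denom = sq.sum(axis=1)
    ok = denom > 0
    table = pd.DataFrame(
        sq[ok] / denom[ok, None], index=frame.index[ok], columns=frame.columns
    )
    return ScoreTable(table, axis, "squared_cosine")


def top_drivers(t: ScoreTable, component: str | int, n: int) -> list[tuple[str, float]]:
    """Top-n entities for a component, descending score, ties broken by id."""
    if isinstance(component, int):
        component = f"PC{component}"
    col = t.frame[component]
    order = sorted(col.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [(str(e), float(s)) for e, s in order[:n]]


def key_components(t: ScoreTable, entity: str, n: int) -> pd.DataFrame:
    """Top-n components for one entity by squared cosine, with cumulative score."""
    if entity not in t.frame.index:
        raise KeyError(f"entity {entity!r} not present in score table")
    row = t.frame.loc[entity]
    order = sorted(row.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n]
    out = pd.DataFrame(order, columns=["component", "score"])
    out["cumulative"] = out["score"].cumsum()
    return out


def group_contribution(t: ScoreTable, groups: Mapping[str, str]) -> ScoreTable:
    """Aggregate phenotype contributions into display groups (unmapped -> 'other')."""
    labels = [groups.get(p, "other") for p in t.frame.index]
    frame = t.frame.groupby(pd.Index(labels, name="group")).sum()
    return ScoreTable(frame, "phenotype_group", "contribution")


def collapse_small_segments(
    t: ScoreTable, component: str | int, threshold: float = 0.005
) -> pd.Series:
    """Stacked-bar data: entities above the display threshold plus an 'others' rest.

    Default threshold 0.005 suits phenotype bars; use 0.0005 for gene bars.
    """
    if isinstance(component, int):
        component = f"PC{component}"
    col = t.frame[component].sort_values(ascending=False)
    big = col[col >= threshold]
    rest = float(col[col < threshold].sum())
    out = big.copy()
    if rest > 0:
        out.loc["others"] = rest
    return out


def biplot_frame(
    d,
    f: FactorScores,
    selected_phenotypes: Sequence[str],
    cx: str | int,
    cy: str | int,
) -> pd.DataFrame:
    """Plot-ready rows for a biplot of two components.

    Phenotype and variant points carry factor-score coordinates; selected
    phenotypes additionally contribute singular-vector arrows (U entries,
    drawn on sub-axes).  The inner product of a variant point with an arrow
    gives the direction and strength of that pair's projected association;
    it is zero for orthogonal pairs or zero-length arrows.
    """
    d = _result(d)
    cx = f"PC{cx}" if isinstance(cx, int) else cx
    cy = f"PC{cy}" if isinstance(cy, int) else cy
    if cx == cy:
        raise ValueError("cx and cy must differ")
    comp = d.component_labels()
    U = pd.DataFrame(d.U, index=f.phenotype.index, columns=comp)
    rows = []
    for pid in f.phenotype.index:
        rows.append(("phenotype_point", pid, f.phenotype.loc[pid, cx], f.phenotype.loc[pid, cy]))
    for vid in f.variant.index:
        rows.append(("variant_point", vid, f.variant.loc[vid, cx], f.variant.loc[vid, cy]))
    for pid in selected_phenotypes:
        if pid not in U.index:
            raise KeyError(f"phenotype {pid!r} not present")
        rows.append(("arrow", pid, U.loc[pid, cx], U.loc[pid, cy]))
    return pd.DataFrame(rows, columns=["kind", "id", "x", "y"])
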