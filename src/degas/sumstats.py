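"""Ingestion of GWAS summary statistics and assembly of the Z-score matrix.

The input model mirrors PLINK2 ``.glm.linear`` / ``.glm.logistic`` output:
one tab-separated table per phenotype, one row per variant, carrying an
effect estimate (BETA for quantitative traits, OR for binary traits), its
standard error and a p-value.  Records surviving the variant QC,
consequence and value filters are aggregated into a phenotype x variant
matrix of Wald Z-scores (estimate / SE), which is then row-standardised
(zero mean, unit variance per phenotype) before factorisation.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "VariantRecord",
    "PhenotypeRecord",
    "ZMatrix",
    "FormatError",
    "MHC_REGION",
    "read_association_table",
    "read_variant_table",
    "read_phenotype_table",
    "filter_variants_qc",
    "qc_filter_counts",
    "subset_by_consequence",
    "apply_value_filter",
    "filter_phenotypes",
    "build_zscore_matrix",
    "standardize_phenotype_rows",
    "collapse_instances",
]

#: Major histocompatibility complex interval (GRCh37, 1-based inclusive).
#: Excluded from all analyses because of its extreme LD structure.
MHC_REGION = ("6", 25477797, 36448354)

CONSEQUENCES = ("ptv", "coding_nonptv", "noncoding")


class FormatError(ValueError):
    """An input table violates the expected column contract."""


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-phenotype summary statistic.

    ``estimate`` is BETA for quantitative phenotypes and log odds ratio for
    binary phenotypes; the Z-score of the association is ``estimate / se``.
    """

    phenotype_id: str
    variant_id: str
    estimate: float
    se: float
    p_value: float


@dataclass(frozen=True)
class VariantRecord:
    """Variant annotation: position, consequence class, genes and QC fields."""

    variant_id: str
    chrom: str
    pos: int
    consequence: str
    genes: frozenset = field(default_factory=frozenset)
    maf: float = float("nan")
    missingness: float = float("nan")
    hwe_p: float = float("nan")
    ld_pruned_in: bool = True

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r} for {self.variant_id}"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Phenotype metadata: kind, effective sample size and display group."""

    phenotype_id: str
    kind: str  # "binary" | "quantitative"
    n_effective: int
    group: str = "other"

    def __post_init__(self):
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")


def _norm_chrom(chrom) -> str:
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_association_table(path, phenotype_id: str, kind: str) -> list[AssociationRecord]:
    """Parse a PLINK2-style association table into records.

    The table must carry an ``ID`` column, a ``P`` column, an ``SE`` (or
    ``LOG(OR)_SE``) column, and exactly one effect column: ``BETA``
    (quantitative) or ``OR`` (binary, log-transformed on ingest).  Rows with
    missing or non-numeric statistics are dropped and counted in the log.
    """
    if kind not in ("binary", "quantitative"):
        raise ValueError(f"unknown phenotype kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.lstrip("#") for c in df.columns]

    for col in ("ID", "P"):
        if col not in df.columns:
            raise FormatError(f"{path}: mandatory column {col!r} is missing")
    se_col = "SE" if "SE" in df.columns else "LOG(OR)_SE"
    if se_col not in df.columns:
        raise FormatError(f"{path}: mandatory column 'SE' is missing")

    has_beta, has_or = "BETA" in df.columns, "OR" in df.columns
    if has_beta and has_or:
        raise FormatError(f"{path}: both BETA and OR present; exactly one expected")
    if not (has_beta or has_or):
        raise FormatError(f"{path}: mandatory column 'BETA' (or 'OR') is missing")
    est_col = "BETA" if has_beta else "OR"

    est = pd.to_numeric(df[est_col], errors="coerce")
    se = pd.to_numeric(df[se_col], errors="coerce")
    p = pd.to_numeric(df["P"], errors="coerce")
    ok = est.notna() & se.notna() & p.notna() & (se > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d rows with missing/invalid statistics", path, n_dropped
        )
    records = []
    for vid, e, s, pv in zip(df.loc[ok, "ID"], est[ok], se[ok], p[ok]):
        if has_or:
            if e <= 0:
                logger.warning("%s: dropped row %s with non-positive OR", path, vid)
                continue
            e = math.log(e)
        records.append(AssociationRecord(phenotype_id, str(vid), float(e), float(s), float(pv)))
    return records


def read_variant_table(path) -> list[VariantRecord]:
    """Read a variant-annotation TSV.

    Expected columns: ID, CHROM, POS, CONSEQUENCE, GENES (comma-separated,
    may be empty), MAF, MISSINGNESS, HWE_P, LD_PRUNED (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["ID", "CHROM", "POS", "CONSEQUENCE", "GENES", "MAF", "MISSINGNESS", "HWE_P", "LD_PRUNED"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: mandatory column {col!r} is missing")
    out = []
    for row in df.itertuples(index=False):
        genes = frozenset(g for g in str(row.GENES).split(",") if g and g != "nan")
        out.append(
            VariantRecord(
                variant_id=str(row.ID),
                chrom=_norm_chrom(row.CHROM),
                pos=int(row.POS),
                consequence=str(row.CONSEQUENCE),
                genes=genes,
                maf=float(row.MAF),
                missingness=float(row.MISSINGNESS),
                hwe_p=float(row.HWE_P),
                ld_pruned_in=str(row.LD_PRUNED) in ("1", "True", "true"),
            )
        )
    return out


def read_phenotype_table(path) -> list[PhenotypeRecord]:
    """Read phenotype metadata TSV with columns ID, KIND, N_EFFECTIVE, GROUP."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("ID", "KIND", "N_EFFECTIVE"):
        if col not in df.columns:
            raise FormatError(f"{path}: mandatory column {col!r} is missing")
    group = df["GROUP"] if "GROUP" in df.columns else pd.Series(["other"] * len(df))
    return [
        PhenotypeRecord(str(i), str(k), int(n), str(g))
        for i, k, n, g in zip(df["ID"], df["KIND"], df["N_EFFECTIVE"], group)
    ]


# ---------------------------------------------------------------------------
# Filters


def _check_qc_fields(v: VariantRecord) -> None:
    for name in ("maf", "missingness", "hwe_p"):
        if math.isnan(getattr(v, name)):
            raise ValueError(f"variant {v.variant_id}: QC field {name!r} is missing")


def filter_variants_qc(
    variants: Iterable[VariantRecord],
    *,
    max_missingness: float = 0.01,
    min_maf: float = 0.0001,
    min_hwe_p: float = 1e-7,
    require_ld_pruned: bool = True,
    exclude_mhc: bool = True,
) -> set:
    """Return variant ids passing the standard QC filter.

    Keeps variants with missingness < 1%, MAF > 0.01%, HWE p > 1e-7,
    membership in the LD-pruned set, and position outside the MHC region
    (chr6:25477797-36448354, 1-based inclusive).
    """
    kept = set()
    mhc_chrom, mhc_lo, mhc_hi = MHC_REGION
    for v in variants:
        _check_qc_fields(v)
        if v.missingness >= max_missingness:
            continue
        if v.maf <= min_maf:
            continue
        if v.hwe_p <= min_hwe_p:
            continue
        if require_ld_pruned and not v.ld_pruned_in:
            continue
        if exclude_mhc and v.chrom == mhc_chrom and mhc_lo <= v.pos <= mhc_hi:
            continue
        kept.add(v.variant_id)
    return kept


def qc_filter_counts(variants: Sequence[VariantRecord]) -> dict:
    """Count, per QC rule, how many variants fail it (rules applied in isolation)."""
    mhc_chrom, mhc_lo, mhc_hi = MHC_REGION
    counts = {"missingness": 0, "maf": 0, "hwe": 0, "ld_pruned": 0, "mhc": 0}
    for v in variants:
        _check_qc_fields(v)
        if v.missingness >= 0.01:
            counts["missingness"] += 1
        if v.maf <= 0.0001:
            counts["maf"] += 1
        if v.hwe_p <= 1e-7:
            counts["hwe"] += 1
        if not v.ld_pruned_in:
            counts["ld_pruned"] += 1
        if v.chrom == mhc_chrom and mhc_lo <= v.pos <= mhc_hi:
            counts["mhc"] += 1
    return counts


def subset_by_consequence(
    variant_ids: set,
    annotations: Mapping[str, VariantRecord],
    dataset: str,
) -> set:
    """Restrict a variant set to a consequence class.

    ``all`` is the identity; ``coding`` keeps PTVs plus other coding
    consequences; ``ptv`` keeps protein-truncating variants only (stop gain,
    frameshift, splice acceptor/donor).
    """
    if dataset == "all":
        return set(variant_ids)
    if dataset == "coding":
        keep = {"ptv", "coding_nonptv"}
    elif dataset == "ptv":
        keep = {"ptv"}
    else:
        raise ValueError(f"unknown dataset label {dataset!r}; expected all|coding|ptv")
    return {v for v in variant_ids if annotations[v].consequence in keep}


def apply_value_filter(
    records: Iterable[AssociationRecord],
    kinds: Mapping[str, str],
    *,
    p_max: float = 0.001,
    se_max_quantitative: float = 0.08,
    se_max_binary: float = 0.2,
) -> list[AssociationRecord]:
    """Keep associations with p < 0.001 and SE below the per-kind cap.

    The SE cap is 0.08 for quantitative phenotypes (BETA scale) and 0.2 for
    binary phenotypes (log-OR scale); everything else is removed.
    """
    out = []
    for r in records:
        kind = kinds[r.phenotype_id]
        cap = se_max_quantitative if kind == "quantitative" else se_max_binary
        if r.p_value < p_max and r.se < cap:
            out.append(r)
    return out


def filter_phenotypes(
    phenotypes: Iterable[PhenotypeRecord], *, min_n: int = 100
) -> list[PhenotypeRecord]:
    """Keep phenotypes with >= 100 cases (binary) or non-missing values (quantitative)."""
    return [p for p in phenotypes if p.n_effective >= min_n]


# ---------------------------------------------------------------------------
# Matrix assembly


@dataclass
class ZMatrix:
    """Phenotype x variant matrix of association Z-scores with axis labels."""

    values: np.ndarray
    phenotype_ids: list
    variant_ids: list
    standardized: bool = False

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.phenotype_ids, columns=self.variant_ids)

    def write(self, prefix) -> None:
        """Serialise as a dense TSV plus two axis-label files (lossless floats)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(
            prefix.with_suffix(".tsv"), sep="\t", float_format="%.17g",
            index_label="phenotype_id",
        )
        Path(str(prefix) + ".phenotypes.txt").write_text(
            "\n".join(map(str, self.phenotype_ids)) + "\n"
        )
        Path(str(prefix) + ".variants.txt").write_text(
            "\n".join(map(str, self.variant_ids)) + "\n"
        )

    @classmethod
    def read(cls, prefix, standardized: bool = False) -> "ZMatrix":
        prefix = Path(prefix)
        df = pd.read_csv(
            prefix.with_suffix(".tsv"), sep="\t", index_col="phenotype_id",
            float_precision="round_trip",
        )
        return cls(
            values=df.to_numpy(dtype=float),
            phenotype_ids=[str(i) for i in df.index],
            variant_ids=[str(c) for c in df.columns],
            standardized=standardized,
        )


def build_zscore_matrix(
    records: Sequence[AssociationRecord],
    phenotypes: Sequence[str],
    variants: Sequence[str],
) -> ZMatrix:
    """Aggregate filtered records into the unstandardised Z-score matrix W.

    Entry (i, j) is ``estimate / se`` where a surviving record exists and 0
    otherwise (the declared sparsity convention).  Phenotypes or variants
    with no surviving record are dropped from the axes, so the coding/PTV
    matrices come out smaller than the all-variants matrix.
    """
    phen_idx = {p: i for i, p in enumerate(phenotypes)}
    var_idx = {v: j for j, v in enumerate(variants)}
    values = np.zeros((len(phenotypes), len(variants)))
    seen = set()
    for r in records:
        if r.phenotype_id not in phen_idx or r.variant_id not in var_idx:
            raise ValueError(
                f"record ({r.phenotype_id}, {r.variant_id}) is outside the retained axes"
            )
        key = (r.phenotype_id, r.variant_id)
        if key in seen:
            raise ValueError(f"duplicate association record for {key}")
        seen.add(key)
        if r.se <= 0:
            raise ValueError(f"non-positive SE for {key}")
        values[phen_idx[r.phenotype_id], var_idx[r.variant_id]] = r.estimate / r.se

    row_keep = np.flatnonzero(np.any(values != 0, axis=1))
    col_keep = np.flatnonzero(np.any(values != 0, axis=0))
    return ZMatrix(
        values=values[np.ix_(row_keep, col_keep)],
        phenotype_ids=[phenotypes[i] for i in row_keep],
        variant_ids=[variants[j] for j in col_keep],
        standardized=False,
    )


def standardize_phenotype_rows(z: ZMatrix, tol: float = 0.0) -> ZMatrix:
    """Centre and scale each phenotype row to zero mean and unit variance.

    Uses the population (1/M) variance.  Constant rows, for which the
    transform is undefined, are dropped with a warning.
    """
    if z.standardized:
        raise ValueError("matrix is already standardized")
    values = np.asarray(z.values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population scaling (ddof=0)
    keep = sd[:, 0] > tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [z.phenotype_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropped {n_dropped} constant phenotype row(s): {dropped[:5]}",
            stacklevel=2,
        )
    out = (values[keep] - mu[keep]) / sd[keep]
    return ZMatrix(
        values=out,
        phenotype_ids=[p for p, k in zip(z.phenotype_ids, keep) if k],
        variant_ids=list(z.variant_ids),
        standardized=True,
    )


def collapse_instances(long_df: pd.DataFrame, kind: str) -> pd.Series:
    """Collapse repeated assessment instances into one value per individual.

    Input is long format with columns ``individual_id``, ``instance``,
    ``value``.  Binary phenotypes are case if the individual is a case in
    any instance; quantitative phenotypes take the median of non-missing
    values.
    """
    if kind == "binary":
        return long_df.groupby("individual_id")["value"].max()
    if kind == "quantitative":
        return long_df.groupby("individual_id")["value"].median()
    raise ValueError(f"unknown phenotype kind {kind!r}")
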