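"""Truncated SVD of the Z-score matrix and component-count selection.

The standardized phenotype x variant matrix W is factorised as
W ~= U S V^T with K components.  Singular values quantify component
magnitude; ``s_k^2 / Var_Tot(W)`` is the fraction of total variance
(squared Frobenius norm) the k-th component explains.  The number of
components worth keeping is judged against the null expectation computed
from the rank of W, capped at K=100 for efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse.linalg
from sklearn.base import BaseEstimator

from .sumstats import ZMatrix

__all__ = [
    "DecompositionResult",
    "DeGAs",
    "truncated_svd",
    "canonicalize_signs",
    "variance_explained",
    "null_expected_variance",
    "select_component_count",
    "median_impute",
    "decompose_phenotype_matrix",
]


@dataclass
class DecompositionResult:
    """Leading-K singular triplets of W plus its total variance.

    U (N x K) holds phenotype singular vectors, V (M x K) variant singular
    vectors, S the non-increasing positive singular values.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    total_variance: float
    phenotype_ids: list = field(default_factory=list)
    variant_ids: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.S)

    def component_labels(self) -> list:
        return [f"PC{i + 1}" for i in range(self.k)]

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.V.T

    def write(self, out_dir, header: str | None = None) -> None:
        """Write U, S, V and the scree table as labelled TSVs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        comp = self.component_labels()
        phen = self.phenotype_ids or [f"row{i}" for i in range(self.U.shape[0])]
        var = self.variant_ids or [f"col{j}" for j in range(self.V.shape[0])]

        def _write(df: pd.DataFrame, name: str, index_label: str):
            path = out_dir / name
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, sep="\t", float_format="%.17g", index_label=index_label)

        _write(pd.DataFrame(self.U, index=phen, columns=comp), "U.tsv", "phenotype_id")
        _write(pd.DataFrame(self.V, index=var, columns=comp), "V.tsv", "variant_id")
        frac = variance_explained(self)
        scree = pd.DataFrame(
            {
                "singular_value": self.S,
                "variance_explained": frac,
                "cumulative": np.cumsum(frac),
            },
            index=comp,
        )
        _write(scree, "scree.tsv", "component")


def canonicalize_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix each component's sign so its largest-|u| phenotype entry is positive.

    The flip is mirrored in V, so U S V^T is unchanged.  Idempotent.
    """
    U = U.copy()
    V = V.copy()
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    return U, V


def _as_array(w) -> tuple[np.ndarray, list, list]:
    if isinstance(w, ZMatrix):
        return np.asarray(w.values, dtype=float), list(w.phenotype_ids), list(w.variant_ids)
    arr = np.asarray(w, dtype=float)
    return arr, [], []


def truncated_svd(w, k: int, seed: int = 0) -> DecompositionResult:
    """Leading-k singular triplets of ``w`` (ZMatrix or array).

    Uses ARPACK's implicitly restarted Lanczos iteration for large inputs
    and a dense LAPACK SVD when k is close to full rank; results are
    deterministic given ``seed`` and canonical up to the documented sign
    convention.
    """
    values, phen, var = _as_array(w)
    n, m = values.shape
    if k <= 0 or k > min(n, m):
        raise ValueError(f"k={k} must be in [1, min(N,M)={min(n, m)}]")

    if k >= min(n, m) - 1 or min(n, m) <= 100:
        U, s, Vt = np.linalg.svd(values, full_matrices=False)
        U, s, V = U[:, :k], s[:k], Vt[:k].T
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n, m))
        U, s, Vt = scipy.sparse.linalg.svds(values, k=k, v0=v0, which="LM")
        order = np.argsort(s)[::-1]
        U, s, V = U[:, order], s[order], Vt[order].T

    pos = s > 0
    U, s, V = U[:, pos], s[pos], V[:, pos]
    U, V = canonicalize_signs(U, V)
    return DecompositionResult(
        U=U,
        S=s,
        V=V,
        total_variance=float(np.sum(values**2)),
        phenotype_ids=phen,
        variant_ids=var,
    )


def variance_explained(d: DecompositionResult) -> np.ndarray:
    """Fraction of total variance explained per component: s_k^2 / Var_Tot(W)."""
    if d.total_variance <= 0:
        raise ValueError("total variance must be positive")
    return d.S**2 / d.total_variance


def null_expected_variance(rank: int, uniform: bool = False) -> float:
    """Expected per-component variance-explained under the null.

    Default is ``1 / rank**2``; ``uniform=True`` switches to the flat-spectrum
    value ``1 / rank`` (where each of the rank components explains an equal
    share).
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    return 1.0 / rank if uniform else 1.0 / rank**2


def select_component_count(
    d: DecompositionResult, rank: int, k_max: int = 100, uniform: bool = False
) -> int:
    """Largest k (capped at k_max) whose variance explained beats the null."""
    frac = variance_explained(d)
    null = null_expected_variance(rank, uniform=uniform)
    above = np.flatnonzero(frac > null)
    if len(above) == 0:
        return 0
    return int(min(k_max, above[-1] + 1))


class DeGAs(BaseEstimator):
    """Decomposition of genetic associations via truncated SVD.

    Fits the leading ``n_components`` singular triplets of a standardized
    phenotype x variant Z-score matrix.  Downstream scores (contribution,
    squared cosine) are computed from the fitted result by the
    :mod:`degas.scores` functions.

    Parameters
    ----------
    n_components : int, default 100
        Number of latent components K to retain.
    random_state : int, default 0
        Seed for the iterative solver's start vector.

    Attributes
    ----------
    result_ : DecompositionResult
        U, S, V and the total variance of the fitted matrix.
    U_ : ndarray of shape (N, K)
        Phenotype singular vectors.
    singular_values_ : ndarray of shape (K,)
    V_ : ndarray of shape (M, K)
        Variant singular vectors.
    explained_variance_ratio_ : ndarray of shape (K,)
    """

    def __init__(self, n_components: int = 100, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        values, _, _ = _as_array(X)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("X must be a non-empty 2-D matrix")
        k = min(self.n_components, min(values.shape))
        self.result_ = truncated_svd(X, k, seed=self.random_state)
        self.U_ = self.result_.U
        self.singular_values_ = self.result_.S
        self.V_ = self.result_.V
        self.components_ = self.result_.V.T
        self.total_variance_ = self.result_.total_variance
        self.explained_variance_ratio_ = variance_explained(self.result_)
        self.n_components_ = self.result_.k
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.U_ * self.singular_values_

    def transform(self, X):
        """Project rows (phenotype Z-score vectors) onto the variant components."""
        values, _, _ = _as_array(X)
        return values @ self.V_

    def select_k(self, rank: int | None = None, uniform: bool = False) -> int:
        """Informative-component count against the null expectation."""
        if rank is None:
            rank = self.U_.shape[0]
        return select_component_count(
            self.result_, rank, k_max=self.n_components, uniform=uniform
        )


def median_impute(X) -> np.ndarray:
    """Replace missing entries with the per-column median of observed values."""
    X = np.array(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValueError(f"column {j} has no observed values")
        col[miss] = np.median(col[~miss])
    return X


def decompose_phenotype_matrix(P, k: int, seed: int = 0) -> DecompositionResult:
    """TSVD of an individuals x phenotypes matrix with missing values.

    Columns are median-imputed, then Z-scored (zero mean, unit population
    variance), then factorised; the left factor scores are the individual
    principal components.
    """
    X = median_impute(P)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns carry no signal; leave centred at 0
    return truncated_svd((X - mu) / sd, k, seed=seed)
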