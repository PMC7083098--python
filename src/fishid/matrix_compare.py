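"""Comparison statistics for among-individual covariance matrices.

Three complementary (dis)similarity measures between two species' ID
matrices:

* ``delta_trace`` — the absolute difference of traces (total among-individual
  variance), |tr(ID1) − tr(ID2)|;
* ``vector_angle`` — the angle θ between the leading eigenvectors (ID_max),
  folded into [0°, 90°] because eigenvector sign is arbitrary;
* ``krzanowski_K`` — the Krzanowski common-subspace similarity between the
  x-dimensional leading eigenspaces, K = Σ eigenvalues of AᵀBBᵀA
  (= Σ cos² of the principal angles between the subspaces), with
  0 ≤ K ≤ x and x ≤ n/2; reported as the dissimilarity x − K.

Confidence intervals come from paired independent draws of two species'
parametric-bootstrap ensembles (2.5/97.5 percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_models import BootstrapEnsemble

__all__ = [
    "trace", "delta_trace", "vector_angle", "krzanowski_K",
    "EigenSummary", "eigen_summary", "SubspaceBasis", "subspace_basis",
    "subspace_basis_from_vectors", "PairwiseTable", "pairwise_statistic_table",
]


def trace(id_matrix) -> float:
    """Sum of diagonal elements (total variance over traits)."""
    m = np.asarray(id_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    return float(np.trace(m))


@dataclass
class EigenSummary:
    """Eigendecomposition of a covariance matrix, eigenvalues descending."""

    values: np.ndarray        # descending
    vectors: np.ndarray       # unit columns, vectors[:, k] pairs values[k]
    percents: np.ndarray      # 100 * value / sum(values)
    degenerate: np.ndarray    # flags for near-ties |λ_k − λ_{k+1}| < tol

    @property
    def leading(self) -> np.ndarray:
        return self.vectors[:, 0]


def eigen_summary(matrix, tie_tol: float = 1e-8) -> EigenSummary:
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    total = w.sum()
    percents = 100.0 * w / total if total != 0 else np.zeros_like(w)
    gaps = np.abs(np.diff(w))
    degenerate = np.zeros(len(w), dtype=bool)
    degenerate[:-1] |= gaps < tie_tol
    degenerate[1:] |= gaps < tie_tol
    # sign convention: largest-magnitude loading positive
    for k in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, k]))
        if v[i, k] < 0:
            v[:, k] = -v[:, k]
    return EigenSummary(values=w, vectors=v, percents=percents,
                        degenerate=degenerate)


def vector_angle(v1, v2) -> float:
    """Angle in degrees between two axes, folded into [0, 90].

    Uses the absolute dot product, so the result is invariant to sign flips
    and rescaling of either vector (eigenvector sign is arbitrary).
    """
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(a @ b)) / (na * nb)
    return float(np.degrees(np.arccos(min(c, 1.0))))


@dataclass
class SubspaceBasis:
    """An x-dimensional orthonormal basis of n-dimensional trait space."""

    basis: np.ndarray     # n x x, orthonormal columns

    def __post_init__(self):
        B = np.asarray(self.basis, dtype=float)
        if B.ndim != 2:
            raise ValueError("basis must be a 2-D array of column vectors")
        n, x = B.shape
        if x > n // 2:
            raise ValueError(f"subspace dimension x={x} exceeds n/2={n // 2}")
        if not np.allclose(B.T @ B, np.eye(x), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")
        self.basis = B

    @property
    def n(self):
        return self.basis.shape[0]

    @property
    def x(self):
        return self.basis.shape[1]


def subspace_basis(matrix, x: int = 2) -> SubspaceBasis:
    """Leading-x eigenvector basis of a covariance matrix."""
    es = eigen_summary(matrix)
    return SubspaceBasis(es.vectors[:, :x])


def subspace_basis_from_vectors(vectors, x: int = 2) -> SubspaceBasis:
    """Orthonormalized basis from (possibly rounded) printed eigenvectors.

    Printed loadings carry rounding so their columns are renormalized and
    Gram-Schmidt orthogonalized (QR), keeping the printed directions.
    """
    V = np.asarray(vectors, dtype=float)[:, :x]
    Q, Rm = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(Rm))
    return SubspaceBasis(Q)


def krzanowski_K(basis1: SubspaceBasis, basis2: SubspaceBasis) -> float:
    """Krzanowski subspace similarity K = Σ eigenvalues of AᵀBBᵀA ∈ [0, x]."""
    A, B = basis1.basis, basis2.basis
    if A.shape != B.shape:
        raise ValueError("bases must share trait dimension n and subspace "
                         "dimension x")
    S = A.T @ B @ B.T @ A
    return float(np.clip(np.trace(S), 0.0, A.shape[1]))


def delta_trace(id1, id2, ens1: BootstrapEnsemble = None,
                ens2: BootstrapEnsemble = None):
    """|Δ| of traces with an optional paired-bootstrap 95% CI.

    The CI is the 2.5/97.5 percentile band of tr(draw1) − tr(draw2) over
    paired draws of the two independent ensembles; significance is read as
    the CI excluding zero.
    """
    point = abs(trace(id1) - trace(id2))
    if ens1 is None or ens2 is None:
        return point, None
    if ens1.n_draws == 0 or ens2.n_draws == 0:
        raise ValueError("empty bootstrap ensemble")
    k = min(ens1.n_draws, ens2.n_draws)
    d = (np.trace(ens1.draws[:k], axis1=1, axis2=2)
         - np.trace(ens2.draws[:k], axis1=1, axis2=2))
    lo, hi = np.percentile(d, [2.5, 97.5])
    return point, (float(lo), float(hi))


@dataclass
class PairwiseTable:
    """Symmetric species-by-species table of a (dis)similarity statistic."""

    species: list
    statistic: str                    # 'delta' | 'theta' | 'two_k' | 'patristic'
    values: pd.DataFrame              # symmetric, zero diagonal
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values
        if not np.allclose(v.to_numpy(), v.to_numpy().T, atol=1e-10):
            raise ValueError("pairwise table must be symmetric")

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in canonical (sorted-label) pair order."""
        sp = sorted(self.species)
        out = []
        for i, a in enumerate(sp):
            for b in sp[i + 1:]:
                out.append(self.values.loc[a, b])
        return np.array(out)

    def to_long(self) -> pd.DataFrame:
        sp = sorted(self.species)
        rows = []
        for i, a in enumerate(sp):
            for b in sp[i + 1:]:
                row = {"species_a": a, "species_b": b,
                       "stat": self.statistic,
                       "point": self.values.loc[a, b]}
                row["lo"] = self.ci_low.loc[a, b] if self.ci_low is not None else np.nan
                row["hi"] = self.ci_high.loc[a, b] if self.ci_high is not None else np.nan
                rows.append(row)
        return pd.DataFrame(rows)

    def to_lower_triangle_csv(self, path, decimals: int = 3):
        """Lower-triangle layout with "point (lower, upper)" cells."""
        sp = list(self.species)
        out = pd.DataFrame("", index=sp[1:], columns=sp[:-1])
        for i, a in enumerate(sp):
            for j, b in enumerate(sp):
                if j >= i:
                    continue
                pt = self.values.loc[a, b]
                cell = f"{pt:.{decimals}f}"
                if self.ci_low is not None:
                    cell += (f" ({self.ci_low.loc[a, b]:.{decimals}f}, "
                             f"{self.ci_high.loc[a, b]:.{decimals}f})")
                out.loc[a, b] = cell
        out.to_csv(path)


def _pair_stat(id1, id2, statistic: str, x: int = 2) -> float:
    if statistic == "delta":
        return abs(trace(id1) - trace(id2))
    if statistic == "theta":
        return vector_angle(eigen_summary(id1).leading, eigen_summary(id2).leading)
    if statistic == "two_k":
        return x - krzanowski_K(subspace_basis(id1, x), subspace_basis(id2, x))
    raise ValueError(f"unknown statistic {statistic!r}")


def pairwise_statistic_table(id_matrices: dict, statistic: str,
                             ensembles: dict | None = None, x: int = 2,
                             with_ci: bool = None) -> PairwiseTable:
    """All-pairs table of Δ, θ, or x−K with optional bootstrap CIs.

    Parameters
    ----------
    id_matrices : dict
        species -> point-estimate ID matrix.
    ensembles : dict, optional
        species -> :class:`BootstrapEnsemble`; required when CIs are wanted.
        Draw *i* of one species is paired with draw *i* of the other
        (ensembles are independent across species by construction).
    """
    sp = sorted(id_matrices)
    if len(sp) < 2:
        raise ValueError("need at least two species")
    if with_ci is None:
        with_ci = ensembles is not None
    if with_ci and (ensembles is None or any(s not in ensembles for s in sp)):
        raise ValueError("CIs requested but ensembles missing for some species")
    vals = pd.DataFrame(0.0, index=sp, columns=sp)
    lo = pd.DataFrame(0.0, index=sp, columns=sp) if with_ci else None
    hi = pd.DataFrame(0.0, index=sp, columns=sp) if with_ci else None
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            pt = _pair_stat(id_matrices[a], id_matrices[b], statistic, x)
            vals.loc[a, b] = vals.loc[b, a] = pt
            if with_ci:
                ea, eb = ensembles[a], ensembles[b]
                k = min(ea.n_draws, eb.n_draws)
                if k == 0:
                    raise ValueError("empty bootstrap ensemble")
                if statistic == "delta":
                    d = (np.trace(ea.draws[:k], axis1=1, axis2=2)
                         - np.trace(eb.draws[:k], axis1=1, axis2=2))
                else:
                    d = np.array([_pair_stat(ea.draws[m], eb.draws[m],
                                             statistic, x) for m in range(k)])
                qlo, qhi = np.percentile(d, [2.5, 97.5])
                lo.loc[a, b] = lo.loc[b, a] = qlo
                hi.loc[a, b] = hi.loc[b, a] = qhi
    return PairwiseTable(species=sp, statistic=statistic, values=vals,
                         ci_low=lo, ci_high=hi)
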