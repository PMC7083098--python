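"""Published reference estimates for the seven-species open-field-trial study.

These are the point estimates reported by the comparative study this package
reanalyses: eigen-decompositions (first two eigenvectors, eigenvalues and
percent variance) of each species' among-individual covariance matrix ``ID``,
the pairwise comparison statistics derived from them (trace difference |Δ|,
leading-eigenvector angle θ, and two-dimensional Krzanowski dissimilarity
2−K), and the phylogenetic distance matrix (substitutions per site) among the
species. They serve two purposes:

* inputs for the *comparison-only* workflow, which re-derives the pairwise
  tables and the phylogenetic-signal statistic from the printed
  eigen-decompositions without access to the raw trial data; and
* targets for the synthetic-data generator, whose default species
  configurations reproduce this eigenstructure.

Note the printed loadings carry rounding, so vectors are renormalized (and,
for subspace work, re-orthonormalized) before use.  One internal
inconsistency of the reference tables is known: the printed θ for
*D. rerio*–*P. reticulata* (73.1°) does not follow from the printed loadings
of those species (which give 53.1°); it appears to be a typographical
duplicate of neighbouring cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = ["TL", "Act", "AC", "TIM"]

#: Canonical (alphabetical) species order used throughout the package.
SPECIES = [
    "Danio rerio",
    "Lima nigrofasciata",
    "Poecilia reticulata",
    "Xenotoca eiseni",
    "Xiphophorus birchmanni",
    "Xiphophorus hellerii",
    "Xiphophorus maculatus",
]

_DR, _LN, _PR, _XE, _XB, _XH, _XM = (
    "Danio rerio",
    "Lima nigrofasciata",
    "Poecilia reticulata",
    "Xenotoca eiseni",
    "Xiphophorus birchmanni",
    "Xiphophorus hellerii",
    "Xiphophorus maculatus",
)

# First (ID_max) and second eigenvectors of each species' ID matrix, with
# eigenvalues (SDU^2) and percent of total among-individual variance.
# Loadings are ordered as TRAITS = (TL, Act, AC, TIM).
EIGEN1 = {
    _DR: {"value": 0.704, "percent": 58.388, "loadings": (0.760, 0.173, 0.469, -0.416)},
    _LN: {"value": 0.261, "percent": 62.010, "loadings": (0.165, 0.354, 0.853, 0.346)},
    _PR: {"value": 0.842, "percent": 57.570, "loadings": (-0.593, -0.436, 0.353, 0.578)},
    _XB: {"value": 0.250, "percent": 60.391, "loadings": (0.563, 0.583, 0.495, 0.314)},
    _XE: {"value": 0.348, "percent": 67.892, "loadings": (0.321, 0.728, 0.310, -0.521)},
    _XH: {"value": 0.305, "percent": 60.352, "loadings": (-0.192, -0.423, 0.134, 0.875)},
    _XM: {"value": 0.706, "percent": 85.349, "loadings": (0.237, 0.383, 0.644, 0.619)},
}

EIGEN2 = {
    _DR: {"value": 0.368, "percent": 30.576, "loadings": (0.192, 0.192, 0.395, 0.878)},
    _LN: {"value": 0.149, "percent": 35.352, "loadings": (0.233, 0.540, 0.057, -0.806)},
    _PR: {"value": 0.407, "percent": 27.785, "loadings": (0.541, 0.357, 0.614, 0.450)},
    _XB: {"value": 0.139, "percent": 34.477, "loadings": (0.376, 0.337, -0.315, -0.804)},
    _XE: {"value": 0.156, "percent": 30.472, "loadings": (0.099, 0.171, 0.682, 0.704)},
    _XH: {"value": 0.178, "percent": 35.313, "loadings": (0.304, 0.615, 0.682, 0.258)},
    _XM: {"value": 0.112, "percent": 13.561, "loadings": (0.333, 0.513, 0.283, -0.739)},
}

#: Pairs whose printed θ is inconsistent with the printed loadings (see
#: module docstring).  Stored in canonical (sorted) order.
THETA_INCONSISTENT_PAIRS = [tuple(sorted((_DR, _PR)))]

# Pairwise tables: unordered species pairs -> published point estimate.
_DELTA = {
    (_DR, _LN): 0.783, (_DR, _PR): 0.258, (_DR, _XB): 0.790, (_DR, _XE): 0.692,
    (_DR, _XH): 0.700, (_DR, _XM): 0.377,
    (_LN, _PR): 1.042, (_LN, _XB): 0.007, (_LN, _XE): 0.091, (_LN, _XH): 0.084,
    (_LN, _XM): 0.406,
    (_PR, _XB): 1.049, (_PR, _XE): 0.951, (_PR, _XH): 0.958, (_PR, _XM): 0.636,
    (_XB, _XE): 0.098, (_XB, _XH): 0.090, (_XB, _XM): 0.413,
    (_XE, _XH): 0.008, (_XE, _XM): 0.315,
    (_XH, _XM): 0.323,
}

_THETA = {
    (_DR, _LN): 63.7, (_DR, _PR): 73.1, (_DR, _XB): 50.9, (_DR, _XE): 42.9,
    (_DR, _XH): 58.7, (_DR, _XM): 73.1,
    (_LN, _PR): 75.6, (_LN, _XB): 33.9, (_LN, _XE): 66.8, (_LN, _XH): 76.4,
    (_LN, _XM): 20.3,
    (_PR, _XB): 76.6, (_PR, _XE): 45.6, (_PR, _XH): 31.6, (_PR, _XM): 73.9,
    (_XB, _XE): 53.5, (_XB, _XH): 89.2, (_XB, _XM): 29.6,
    (_XE, _XH): 38.4, (_XE, _XM): 76.6,
    (_XH, _XM): 65.1,
}

_TWO_K = {
    (_DR, _LN): 0.567, (_DR, _PR): 0.452, (_DR, _XB): 0.365, (_DR, _XE): 0.547,
    (_DR, _XH): 0.482, (_DR, _XM): 0.324,
    (_LN, _PR): 0.464, (_LN, _XB): 0.319, (_LN, _XE): 0.039, (_LN, _XH): 0.066,
    (_LN, _XM): 0.097,
    (_PR, _XB): 0.082, (_PR, _XE): 0.372, (_PR, _XH): 0.379, (_PR, _XM): 0.440,
    (_XB, _XE): 0.194, (_XB, _XH): 0.170, (_XB, _XM): 0.212,
    (_XE, _XH): 0.009, (_XE, _XM): 0.067,
    (_XH, _XM): 0.037,
}

#: Phylogenetic (patristic) distances, substitutions per site.
_PATRISTIC = {
    (_DR, _LN): 0.132, (_DR, _PR): 0.132, (_DR, _XB): 0.132, (_DR, _XE): 0.132,
    (_DR, _XH): 0.132, (_DR, _XM): 0.132,
    (_LN, _PR): 0.029, (_LN, _XB): 0.045, (_LN, _XE): 0.129, (_LN, _XH): 0.045,
    (_LN, _XM): 0.045,
    (_PR, _XB): 0.045, (_PR, _XE): 0.129, (_PR, _XH): 0.045, (_PR, _XM): 0.045,
    (_XB, _XE): 0.129, (_XB, _XH): 0.012, (_XB, _XM): 0.012,
    (_XE, _XH): 0.129, (_XE, _XM): 0.129,
    (_XH, _XM): 0.001,
}

#: Mean standard length (mm) per species.  Only the smallest (P. reticulata,
#: 19.47 mm) and largest (X. eiseni, 48.25 mm) were reported; the others are
#: plausible intermediate values used by the synthetic generator.
MEAN_SL_MM = {
    _DR: 30.0,
    _LN: 35.0,
    _PR: 19.47,
    _XE: 48.25,
    _XB: 40.0,
    _XH: 42.0,
    _XM: 32.0,
}


def leading_eigenvector(species: str) -> np.ndarray:
    """Unit-normalized printed leading eigenvector of ``ID`` for a species."""
    v = np.asarray(EIGEN1[species]["loadings"], dtype=float)
    return v / np.linalg.norm(v)


def eigenvector_pair(species: str) -> np.ndarray:
    """4x2 matrix whose columns are the printed first two eigenvectors.

    Columns are renormalized but *not* orthogonalized; use
    :func:`fishid.matrix_compare.subspace_basis_from_vectors` where an
    orthonormal basis is required.
    """
    v1 = np.asarray(EIGEN1[species]["loadings"], dtype=float)
    v2 = np.asarray(EIGEN2[species]["loadings"], dtype=float)
    return np.column_stack([v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)])


def id_trace(species: str) -> float:
    """Total among-individual variance implied by the printed decomposition.

    The first eigenvalue and its percent of total variance jointly determine
    the trace of ``ID`` (trace = value / (percent/100)).
    """
    e = EIGEN1[species]
    return e["value"] / (e["percent"] / 100.0)


def _pairwise_frame(values: dict) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=SPECIES, columns=SPECIES)
    for (a, b), v in values.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def delta_table() -> pd.DataFrame:
    """Published |Δ| (absolute trace difference) between species pairs."""
    return _pairwise_frame(_DELTA)


def theta_table() -> pd.DataFrame:
    """Published angle θ (degrees) between species' leading eigenvectors."""
    return _pairwise_frame(_THETA)


def two_k_table() -> pd.DataFrame:
    """Published Krzanowski two-dimensional subspace dissimilarity 2−K."""
    return _pairwise_frame(_TWO_K)


def patristic_table() -> pd.DataFrame:
    """Published phylogenetic distance matrix (substitutions per site)."""
    return _pairwise_frame(_PATRISTIC)
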