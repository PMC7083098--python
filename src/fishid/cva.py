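"""Canonical variate analysis of mean behavioral phenotype across species.

Individuals are reduced to their within-individual mean trait vector, then
canonical axes are found that sequentially maximize among-species variance
relative to pooled within-species variance: the generalized eigenproblem
B a = λ W a, with W the pooled within-group covariance and B the (unweighted)
between-group-mean scatter.  Scores are sphered — their pooled within-group
covariance is the identity — and at most min(traits, groups − 1) axes are
returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .reference_tables import TRAITS

__all__ = ["individual_means", "CvaResult", "cva_fit",
           "Ellipse", "confidence_ellipse"]


def individual_means(table: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """One row per individual: its mean trait vector and species label."""
    g = table.groupby(["species", "fish_id"], sort=True)[list(traits)].mean()
    return g.reset_index()


@dataclass
class CvaResult:
    coefficients: np.ndarray    # traits x axes
    percents: np.ndarray        # per-axis share of among-group variance
    eigenvalues: np.ndarray
    scores: pd.DataFrame        # per-individual canonical scores + species
    trait_labels: list
    group_means: pd.DataFrame   # species-mean scores on the canonical axes


def cva_fit(means: pd.DataFrame, traits=TRAITS, group_col: str = "species") -> CvaResult:
    """Canonical variates of per-individual means across labelled groups."""
    traits = list(traits)
    X = means[traits].to_numpy(dtype=float)
    labels = means[group_col].to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n, T = X.shape
    Wss = np.zeros((T, T))
    gm = []
    for g in groups:
        sub = X[labels == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
        c = sub - sub.mean(axis=0)
        Wss += c.T @ c
        gm.append(sub.mean(axis=0))
    W = Wss / (n - len(groups))
    gm = np.array(gm)
    grand = gm.mean(axis=0)         # unweighted by group size
    d = gm - grand
    B = d.T @ d / (len(groups) - 1)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as err:
        raise ValueError("singular within-group covariance; consider removing "
                         "a redundant trait") from err
    order = np.argsort(evals)[::-1]
    n_axes = min(T, len(groups) - 1)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    A = evecs[:, order][:, :n_axes]        # W-orthonormal: A' W A = I
    for k in range(n_axes):                # sign: largest coefficient positive
        i = np.argmax(np.abs(A[:, k]))
        if A[i, k] < 0:
            A[:, k] = -A[:, k]
    total = evals.sum()
    percents = 100.0 * evals / total if total > 0 else np.zeros(n_axes)
    S = (X - grand) @ A
    scores = pd.DataFrame(S, columns=[f"CV{k + 1}" for k in range(n_axes)])
    scores.insert(0, group_col, labels)
    if "fish_id" in means:
        scores.insert(1, "fish_id", means["fish_id"].to_numpy())
    gscores = pd.DataFrame((gm - grand) @ A, index=groups,
                           columns=[f"CV{k + 1}" for k in range(n_axes)])
    return CvaResult(coefficients=A, percents=percents, eigenvalues=evals,
                     scores=scores, trait_labels=traits, group_means=gscores)


@dataclass
class Ellipse:
    """A 2-D confidence ellipse: centre, semi-axes, orientation (radians)."""

    center: np.ndarray
    semi_axes: np.ndarray     # descending
    angle: float              # of the major axis vs the first score axis


def confidence_ellipse(scores, level: float = 0.95) -> Ellipse:
    """Ellipse covering the requested share of a group's 2-D score spread.

    Describes the score distribution itself (covariance scaled by the
    chi-square(2) quantile), not the standard error of the group mean.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if S.shape[0] < 3:
        raise ValueError("need at least 3 points for an ellipse")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    center = S.mean(axis=0)
    cov = np.cov(S.T)
    w, v = np.linalg.eigh(cov)
    if w.min() <= 0:
        raise ValueError("degenerate score covariance")
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    r2 = chi2.ppf(level, df=2) if level > 0 else 0.0
    return Ellipse(center=center, semi_axes=np.sqrt(w * r2),
                   angle=float(np.arctan2(v[1, 0], v[0, 0])))
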