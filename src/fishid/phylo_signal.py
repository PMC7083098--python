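"""Phylogenetic signal in ID-matrix dissimilarity via Kendall tau-b.

Association between the patristic (cophenetic) distance matrix of the
species phylogeny and a behavioral dissimilarity matrix (|Δ|, θ, or x−K) is
summarized by the Mantel-style Kendall tau-b over the 21 unordered species
pairs; tau-b's tie-corrected denominator matters because the distance
matrix has many tied entries.  Uncertainty combines two sources in a nested
bootstrap: each replicate draws one tree from a tree set (posterior sample
or jittered stand-in) and one ID matrix per species from its parametric
bootstrap ensemble, recomputes the dissimilarity table and tau; the 95% CI
is the 2.5/97.5 percentile band over replicates.  Point estimates use a
designated point tree with the point ID estimates — the bootstrap supplies
only the CI.  No permutation p-values are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .matrix_compare import PairwiseTable, _pair_stat

__all__ = ["patristic_distances", "kendall_tau_b",
           "dissimilarity_from_similarity", "SignalResult",
           "signal_bootstrap", "signal_point"]


def patristic_distances(tree: dendropy.Tree, labels=None) -> PairwiseTable:
    """Sum of branch lengths between every pair of leaves.

    ``labels`` restricts and orders the species; all must be tree leaves.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if labels is None:
        labels = sorted(taxa)
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    sp = sorted(labels)
    vals = pd.DataFrame(0.0, index=sp, columns=sp)
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            d = float(pdm.patristic_distance(taxa[a], taxa[b]))
            vals.loc[a, b] = vals.loc[b, a] = d
    return PairwiseTable(species=sp, statistic="patristic", values=vals)


def kendall_tau_b(d1: PairwiseTable, d2: PairwiseTable) -> float:
    """Tau-b rank correlation between two pairwise tables' lower triangles.

    Both tables are vectorized in the same canonical (sorted-label) pair
    order, so any shared ordering yields the same value.  All-tied input on
    either side leaves tau undefined (returned as nan).
    """
    if sorted(d1.species) != sorted(d2.species):
        raise ValueError("tables must cover the same species set")
    x, y = d1.condensed(), d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(kendalltau(x, y, variant="b").statistic)


def dissimilarity_from_similarity(k_table: PairwiseTable, x: int) -> PairwiseTable:
    """Entrywise x − K, turning subspace similarity into dissimilarity.

    With this orientation all three behavioral statistics are
    dissimilarities, so phylogenetic signal predicts positive correlations.
    """
    if k_table.statistic not in ("K", "two_k"):
        raise ValueError(f"expected a Krzanowski table, got {k_table.statistic!r}")
    vals = x - k_table.values
    np.fill_diagonal(vals.values, 0.0)
    tag = "two_k" if k_table.statistic == "K" else "K"
    return PairwiseTable(species=k_table.species, statistic=tag, values=vals)


@dataclass
class SignalResult:
    """Tau-b point estimate with its nested-bootstrap distribution."""

    statistic: str
    tau: float
    ci: tuple
    bootstrap: np.ndarray
    n_reps: int
    n_failed: int
    seed: int

    def to_json_dict(self):
        return {"statistic": self.statistic, "tau": self.tau,
                "ci_low": self.ci[0], "ci_high": self.ci[1],
                "n_reps": self.n_reps, "n_failed": self.n_failed,
                "seed": self.seed}


def signal_point(tree: dendropy.Tree, id_matrices: dict, statistic: str,
                 x: int = 2) -> float:
    """Tau-b between a point tree's distances and point ID dissimilarities."""
    labels = sorted(id_matrices)
    dist = patristic_distances(tree, labels)
    behav = _behavioral_table(id_matrices, statistic, x)
    return kendall_tau_b(dist, behav)


def _behavioral_table(id_matrices: dict, statistic: str, x: int) -> PairwiseTable:
    sp = sorted(id_matrices)
    vals = pd.DataFrame(0.0, index=sp, columns=sp)
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            v = _pair_stat(id_matrices[a], id_matrices[b], statistic, x)
            vals.loc[a, b] = vals.loc[b, a] = v
    return PairwiseTable(species=sp, statistic=statistic, values=vals)


def signal_bootstrap(trees, ensembles: dict, statistic: str,
                     n_reps: int = 1000, seed: int = 0, x: int = 2,
                     point_tree: dendropy.Tree = None,
                     point_ids: dict = None) -> SignalResult:
    """Nested bootstrap of tau-b over tree and ID-matrix uncertainty.

    Each replicate draws one tree (uniformly from ``trees``) and one ID
    draw per species from its ensemble, rebuilds both distance tables and
    computes tau-b.  Replicates yielding an undefined tau (fully tied draw)
    are excluded and counted.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("tree set is empty")
    labels = sorted(ensembles)
    for s, e in ensembles.items():
        if e.n_draws == 0:
            raise ValueError(f"empty ensemble for {s!r}")
    rng = np.random.default_rng(seed)
    dist_cache = {}
    taus = []
    n_failed = 0
    for _ in range(n_reps):
        ti = int(rng.integers(len(trees)))
        if ti not in dist_cache:
            dist_cache[ti] = patristic_distances(trees[ti], labels)
        ids = {s: ensembles[s].draws[int(rng.integers(ensembles[s].n_draws))]
               for s in labels}
        tau = kendall_tau_b(dist_cache[ti], _behavioral_table(ids, statistic, x))
        if np.isnan(tau):
            n_failed += 1
        else:
            taus.append(tau)
    taus = np.array(taus)
    if taus.size == 0:
        raise RuntimeError("all bootstrap replicates degenerate")
    lo, hi = np.percentile(taus, [2.5, 97.5])
    ptree = point_tree if point_tree is not None else trees[0]
    if point_ids is None:   # fall back to ensemble means as point estimates
        point_ids = {s: ensembles[s].draws.mean(axis=0) for s in labels}
    tau_point = signal_point(ptree, point_ids, statistic, x)
    return SignalResult(statistic=statistic, tau=tau_point,
                        ci=(float(lo), float(hi)), bootstrap=taus,
                        n_reps=n_reps, n_failed=n_failed, seed=seed)
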