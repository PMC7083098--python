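"""End-to-end orchestration: preprocess → fits → comparisons → signal.

Runs the full comparative analysis from a single configuration with one
master seed: every random draw (simulation, bootstrap ensembles, tree
jitter, signal replicates) derives from it through numpy ``SeedSequence``
stream splitting, so a run is a pure function of (inputs, config, seed).

A *comparison-only* entry point accepts published eigen-decompositions
instead of raw trial data and re-derives the θ / x−K tables and the
phylogenetic-signal statistics from them alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, matrix_compare, phylo_signal, reference_tables as ref
from .cva import cva_fit, individual_means
from .mixed_models import (fit_multivariate,
                           fit_null_univariate, fit_pair_blocked,
                           fit_univariate, lrt_id_covariances,
                           lrt_id_equality, lrt_mixture_p, parametric_bootstrap,
                           repeatability)
from .preprocessing import preprocess
from .reference_tables import TRAITS

log = logging.getLogger("fishid")


@dataclass
class AnalysisConfig:
    """Inputs, sizes and seed of one full analysis run."""

    trial_table: str | None = None      # path to raw trial CSV, or None to simulate
    tree_file: str | None = None        # newick (single or multi-tree), or None
    simulate: bool = True
    max_individuals: int | None = 150   # desk-scale cap when simulating
    traits: list = field(default_factory=lambda: list(TRAITS))
    n_boot: int = 200                   # bootstrap draws (paper scale: 5000)
    signal_reps: int = 1000
    n_posterior_trees: int = 200
    tree_jitter: float = 0.1
    x: int = 2
    seed: int = 0
    outdir: str = "results"
    do_pair_lrts: bool = True

    def validate(self):
        if self.x > len(self.traits) // 2:
            raise ValueError("subspace dimension x must satisfy x <= traits/2")
        if not self.simulate and self.trial_table is None:
            raise ValueError("either simulate or provide a trial table")
        return self

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text())).validate()

    def paper_scale(self):
        """Bootstrap sizes used by the original analysis."""
        self.n_boot = 5000
        self.signal_reps = 1000
        self.max_individuals = None
        return self


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle."""
    config.validate()
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sim_seed, boot_ss, tree_seed, signal_ss = (
        int(seeds[0].generate_state(1)[0] % 2**31), seeds[1],
        int(seeds[2].generate_state(1)[0] % 2**31), seeds[3])

    if config.simulate:
        sim = datasets.default_simulation_config(
            seed=sim_seed, max_individuals=config.max_individuals)
        raw = datasets.simulate_all(sim)
    else:
        raw = datasets.read_trial_table(config.trial_table)
    log.info("data: %d trials on %d fish, %d species (%.1fs)",
             len(raw), raw["fish_id"].nunique(), raw["species"].nunique(),
             time.time() - t0)

    sdu, scaling = preprocess(raw)
    species = sorted(sdu["species"].unique())
    by_species = {s: sdu[sdu["species"] == s] for s in species}

    # univariate repeatabilities with boundary LRTs
    uni_rows = []
    for s in species:
        for t in config.traits:
            f = fit_univariate(by_species[s], t)
            ll0 = fit_null_univariate(by_species[s], t)
            stat, p = lrt_mixture_p(f.reml_loglik, ll0)
            uni_rows.append({"species": s, "trait": t, "V_I": f.V_I,
                             "V_R": f.V_R, "repeatability": repeatability(f),
                             "lrt_stat": stat, "p": p,
                             "converged": f.converged})
    univariate = pd.DataFrame(uni_rows)
    log.info("univariate fits done (%.1fs)", time.time() - t0)

    # multivariate ID fits + 6-df covariance LRTs + bootstrap ensembles
    fits, ensembles, cov_rows = {}, {}, []
    boot_seeds = boot_ss.spawn(len(species))
    for s, bss in zip(species, boot_seeds):
        full = fit_multivariate(by_species[s], config.traits)
        diag = fit_multivariate(by_species[s], config.traits,
                                constrain_diagonal=True)
        stat, df, p = lrt_id_covariances(full, diag)
        cov_rows.append({"species": s, "lrt_stat": stat, "df": df, "p": p,
                         "converged": full.converged})
        fits[s] = full
        ensembles[s] = parametric_bootstrap(
            full, n_draws=config.n_boot,
            seed=int(bss.generate_state(1)[0] % 2**31))
        log.info("multivariate fit + %d bootstrap draws: %s (%.1fs)",
                 config.n_boot, s, time.time() - t0)
    cov_lrts = pd.DataFrame(cov_rows)

    # pairwise equality LRTs (10 df)
    pair_rows = []
    if config.do_pair_lrts:
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                try:
                    unc = fit_pair_blocked(by_species[a], by_species[b],
                                           config.traits)
                    con = fit_pair_blocked(by_species[a], by_species[b],
                                           config.traits, constrain_equal=True)
                    stat, df, p = lrt_id_equality(unc, con)
                    pair_rows.append({"species_a": a, "species_b": b,
                                      "lrt_stat": stat, "df": df, "p": p,
                                      "converged": unc.converged and con.converged})
                except Exception as err:    # honest failure reporting
                    pair_rows.append({"species_a": a, "species_b": b,
                                      "lrt_stat": np.nan, "df": 10, "p": np.nan,
                                      "converged": False, "error": str(err)})
        log.info("pairwise equality LRTs done (%.1fs)", time.time() - t0)
    pair_lrts = pd.DataFrame(pair_rows)

    id_mats = {s: fits[s].ID for s in species}
    tables = {
        "delta": matrix_compare.pairwise_statistic_table(id_mats, "delta",
                                                         ensembles),
        "theta": matrix_compare.pairwise_statistic_table(id_mats, "theta",
                                                         ensembles),
        "two_k": matrix_compare.pairwise_statistic_table(id_mats, "two_k",
                                                         ensembles, x=config.x),
    }

    cva = cva_fit(individual_means(sdu, config.traits), config.traits)

    base_tree = (datasets.read_trees(config.tree_file)[0]
                 if config.tree_file else datasets.make_reference_tree())
    trees = datasets.simulate_tree_posterior(base_tree,
                                             config.n_posterior_trees,
                                             config.tree_jitter, tree_seed)
    patristic = phylo_signal.patristic_distances(
        base_tree, labels=species if set(species) <=
        {t.label for t in base_tree.taxon_namespace} else None)

    signals = {}
    sseeds = signal_ss.spawn(3)
    for stat_name, sss in zip(("delta", "theta", "two_k"), sseeds):
        signals[stat_name] = phylo_signal.signal_bootstrap(
            trees, ensembles, stat_name, n_reps=config.signal_reps,
            seed=int(sss.generate_state(1)[0] % 2**31), x=config.x,
            point_tree=base_tree, point_ids=id_mats)
    log.info("phylogenetic signal done (%.1fs)", time.time() - t0)

    return {"config": config, "raw": raw, "sdu": sdu, "scaling": scaling,
            "univariate": univariate, "fits": fits, "cov_lrts": cov_lrts,
            "pair_lrts": pair_lrts, "ensembles": ensembles,
            "pairwise": tables, "patristic": patristic, "cva": cva,
            "signals": signals}


def run_comparison_only(eigenvectors: dict = None, tree=None, x: int = 2) -> dict:
    """Re-derive the comparison tables from published eigen-decompositions.

    ``eigenvectors`` maps species -> 4x2 loading matrix (defaults to the
    published reference estimates); ``tree`` defaults to the reference
    phylogeny.  Returns θ and x−K pairwise tables plus tau-b of each against
    the patristic distances (using trace-consistent reconstructed matrices
    for Δ).
    """
    if eigenvectors is None:
        eigenvectors = {s: ref.eigenvector_pair(s) for s in ref.SPECIES}
    species = sorted(eigenvectors)
    if tree is None:
        tree = datasets.make_reference_tree()

    theta = pd.DataFrame(0.0, index=species, columns=species)
    twok = pd.DataFrame(0.0, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            th = matrix_compare.vector_angle(eigenvectors[a][:, 0],
                                             eigenvectors[b][:, 0])
            ka = matrix_compare.subspace_basis_from_vectors(eigenvectors[a], x)
            kb = matrix_compare.subspace_basis_from_vectors(eigenvectors[b], x)
            kv = x - matrix_compare.krzanowski_K(ka, kb)
            theta.loc[a, b] = theta.loc[b, a] = th
            twok.loc[a, b] = twok.loc[b, a] = kv
    theta_tab = matrix_compare.PairwiseTable(species, "theta", theta)
    twok_tab = matrix_compare.PairwiseTable(species, "two_k", twok)
    dist = phylo_signal.patristic_distances(tree, species)
    taus = {"theta": phylo_signal.kendall_tau_b(dist, theta_tab),
            "two_k": phylo_signal.kendall_tau_b(dist, twok_tab)}
    return {"theta": theta_tab, "two_k": twok_tab, "patristic": dist,
            "taus": taus}


def write_tables(results: dict, outdir=None) -> dict:
    """Write every output table; returns {relative name: sha256}."""
    outdir = Path(outdir if outdir is not None else results["config"].outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = results["config"]

    results["univariate"].to_csv(outdir / "repeatabilities.csv", index=False)
    results["cov_lrts"].to_csv(outdir / "id_covariance_lrts.csv", index=False)
    if len(results["pair_lrts"]):
        results["pair_lrts"].to_csv(outdir / "id_equality_lrts.csv", index=False)
    for s, f in results["fits"].items():
        f.to_json(outdir / f"fit_{s.replace(' ', '_')}.json")

    name_map = {"delta": "table1_delta", "theta": "table3_theta",
                "two_k": "table4_twoK"}
    for key, stem in name_map.items():
        tab = results["pairwise"][key]
        tab.to_lower_triangle_csv(outdir / f"{stem}.csv")
        tab.to_long().to_csv(outdir / f"{stem}_long.csv", index=False)
    results["patristic"].to_lower_triangle_csv(outdir / "table5_patristic.csv")
    results["patristic"].to_long().to_csv(outdir / "table5_patristic_long.csv",
                                          index=False)

    cva = results["cva"]
    pd.DataFrame(cva.coefficients, index=cva.trait_labels,
                 columns=[f"CV{k + 1}" for k in range(cva.coefficients.shape[1])]
                 ).to_csv(outdir / "cva_coefficients.csv")
    cva.scores.to_csv(outdir / "cva_scores.csv", index=False)

    sig = {k: v.to_json_dict() for k, v in results["signals"].items()}
    (outdir / "phylo_signal.json").write_text(json.dumps(sig, indent=1))

    hashes = {}
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"seed": cfg.seed, "n_boot": cfg.n_boot,
                "signal_reps": cfg.signal_reps, "x": cfg.x,
                "traits": cfg.traits, "files": hashes}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return hashes
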