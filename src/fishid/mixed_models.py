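"""REML estimation of among-individual (co)variance from repeated measures.

The model for the trait vector of individual *i* on trial *j* is

    y_ij = X_ij beta + u_i + e_ij,   u_i ~ N(0, ID),  e_ij ~ N(0, R)

with fixed effects of repeat (categorical) and within-group order (linear
slope) per trait, a random intercept per individual, an unstructured
among-individual covariance ``ID`` (positive semi-definite) and an
unstructured residual covariance ``R`` (positive definite).  Estimation is by
restricted maximum likelihood: the per-individual marginal covariance
``V_i = I_n (x) R + J_n (x) ID`` (trial-major Kronecker structure) is shared
by all individuals with the same trial count, so the restricted
log-likelihood and its analytic gradient are evaluated group-wise with dense
algebra only in the small ``n*T`` dimension.

(Co)variance matrices are parameterized through Cholesky-type factors during
optimization — ``ID = L L'`` with free entries (so boundary/singular
solutions are admissible) and ``R = L_R L_R'`` with exponential diagonal (so
``R`` stays positive definite).  Symmetry and (semi)definiteness therefore
hold by construction, not by post-hoc clipping.

The same engine serves the univariate fits (T=1), the diagonal-ID reduced
model of the 6-df covariance test, and the shared-ID constrained model of the
10-df pairwise equality test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .reference_tables import TRAITS

__all__ = [
    "UnivariateFit", "MultivariateFit", "BootstrapEnsemble",
    "fit_univariate", "repeatability", "lrt_mixture_p",
    "fit_multivariate", "lrt_id_covariances",
    "fit_pair_blocked", "lrt_id_equality", "parametric_bootstrap",
]


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

class DesignError(ValueError):
    pass


@dataclass
class _Prepared:
    """Per-dataset arrays laid out for group-wise likelihood evaluation."""

    traits: list
    fixed_names: list
    groups: list          # list of (n_trials, Xs (m,nT,q), ys (m,nT))
    fish_ids: list        # individual labels, group-blocked order
    T: int
    p: int
    q: int
    n_individuals: int
    n_obs: int            # number of trials total
    M: int                # scalar observations = n_obs * T
    G0: np.ndarray        # moment starting values
    R0: np.ndarray

    def with_response(self, ys_by_group):
        new = _Prepared(self.traits, self.fixed_names,
                        [(n, Xs, ys) for (n, Xs, _), ys in
                         zip(self.groups, ys_by_group)],
                        self.fish_ids, self.T, self.p, self.q,
                        self.n_individuals, self.n_obs, self.M,
                        self.G0, self.R0)
        return new


def _design_row_builder(table: pd.DataFrame):
    rep = table["repeat"].to_numpy()
    levels = np.unique(rep)
    if levels.size < 2:
        raise DesignError("repeat must have at least 2 levels")
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append((rep == lv).astype(float))
        names.append(f"repeat_{lv}")
    order = table["order_in_group"].to_numpy(dtype=float)
    if np.ptp(order) > 0:
        cols.append(order)
        names.append("order")
    return np.column_stack(cols), names


def _prepare(table: pd.DataFrame, traits) -> _Prepared:
    traits = list(traits)
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise DesignError(f"traits not in table: {missing}")
    tab = table.sort_values(["fish_id", "repeat"], kind="mergesort").reset_index(drop=True)
    X, fixed_names = _design_row_builder(tab)
    Y = tab[traits].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DesignError("trait columns contain missing values")
    T = len(traits)
    p = X.shape[1]
    q = T * p

    ids = tab["fish_id"].to_numpy()
    _, starts = np.unique(ids, return_index=True)
    starts_sorted = np.sort(starts)
    bounds = np.append(starts_sorted, len(tab))
    per_ind = [(bounds[i], bounds[i + 1]) for i in range(len(starts_sorted))]

    by_n = {}
    for a, b in per_ind:
        by_n.setdefault(b - a, []).append((a, b))

    groups, fish_ids = [], []
    mean_list, within_ss, within_df = [], np.zeros((T, T)), 0
    for n, spans in sorted(by_n.items()):
        m = len(spans)
        Xg = np.empty((m, n, p))
        Yg = np.empty((m, n, T))
        for i, (a, b) in enumerate(spans):
            Xg[i] = X[a:b]
            Yg[i] = Y[a:b]
            fish_ids.append(ids[a])
        Xs = np.zeros((m, n * T, q))
        for t in range(T):
            Xs[:, t::T, t * p:(t + 1) * p] = Xg
        ys = Yg.reshape(m, n * T)
        groups.append((n, Xs, ys))
        mu = Yg.mean(axis=1)
        mean_list.append(mu)
        dev = Yg - mu[:, None, :]
        within_ss += np.einsum("mjt,mjs->ts", dev, dev)
        within_df += m * (n - 1)

    means = np.vstack(mean_list)
    n_ind = means.shape[0]
    n_obs = len(tab)
    Sw = within_ss / max(within_df, 1)
    Sb = np.cov(means.T).reshape(T, T) if n_ind > 1 else np.eye(T)
    nbar = n_obs / n_ind
    G0 = Sb - Sw / nbar
    w, V = np.linalg.eigh((G0 + G0.T) / 2)
    floor = 1e-3 * max(np.trace(Sw) / T, 1e-6)
    G0 = (V * np.clip(w, floor, None)) @ V.T
    R0 = Sw + floor * np.eye(T)
    return _Prepared(traits, fixed_names, groups, fish_ids, T, p, q,
                     n_ind, n_obs, n_obs * T, G0, R0)


# ---------------------------------------------------------------------------
# Restricted likelihood and analytic gradient
# ---------------------------------------------------------------------------

def _reml_components(preps, G, Rs, want_grad=True):
    """-2 * restricted log-likelihood summed over datasets, with gradients.

    ``G`` is shared across the datasets in ``preps``; each dataset has its
    own residual covariance ``Rs[d]`` and its own fixed effects (profiled
    out by GLS).  Returns (neg2, grad_G, [grad_R_d], [beta_d]).
    """
    neg2 = 0.0
    gG = np.zeros_like(G)
    gRs = [np.zeros_like(R) for R in Rs]
    betas = []
    for d, (prep, R) in enumerate(zip(preps, Rs)):
        T, q = prep.T, prep.q
        XtViX = np.zeros((q, q))
        XtViy = np.zeros(q)
        ytViy = 0.0
        logdetV = 0.0
        cache = []
        for n, Xs, ys in prep.groups:
            m = Xs.shape[0]
            V = np.kron(np.eye(n), R) + np.kron(np.ones((n, n)), G)
            c, low = cho_factor(V, lower=True)
            logdetV += m * 2.0 * np.log(np.diag(c)).sum()
            Vinv = cho_solve((c, low), np.eye(n * T))
            ViX = np.einsum("ab,mbq->maq", Vinv, Xs, optimize=True)
            XtViX += np.einsum("mai,maj->ij", Xs, ViX, optimize=True)
            Viy = ys @ Vinv
            XtViy += np.einsum("mai,ma->i", Xs, Viy, optimize=True)
            ytViy += float(np.einsum("ma,ma->", ys, Viy))
            cache.append((n, Xs, ys, Vinv, ViX))
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise DesignError("singular fixed-effect information; check design")
        beta = np.linalg.solve(XtViX, XtViy)
        betas.append(beta)
        neg2 += (logdetV + logdetXtViX + (ytViy - XtViy @ beta)
                 + (prep.M - q) * np.log(2.0 * np.pi))
        if not want_grad:
            continue
        W = np.linalg.inv(XtViX)
        for n, Xs, ys, Vinv, ViX in cache:
            m = Xs.shape[0]
            r = ys - Xs @ beta
            u = r @ Vinv                          # V^{-1} r, (m, nT)
            u_r = u.reshape(m, n, T)
            s = u_r.sum(axis=1)                   # Z' V^{-1} r, (m, T)
            Vinv_r = Vinv.reshape(n, T, n, T)
            ZVZ = Vinv_r.sum(axis=(0, 2))
            Q0 = np.einsum("jajb->ab", Vinv_r)
            Bv = ViX.reshape(m, n, T, q)
            A = Bv.sum(axis=1)                    # Z' V^{-1} X_i, (m, T, q)
            AW = np.einsum("mtq,qr->mtr", A, W, optimize=True)
            trG2 = np.einsum("mtr,msr->ts", AW, A, optimize=True)
            BW = np.einsum("mjtq,qr->mjtr", Bv, W, optimize=True)
            trR2 = np.einsum("mjtr,mjsr->ts", BW, Bv, optimize=True)
            gG += m * ZVZ - trG2 - s.T @ s
            gRs[d] += m * Q0 - trR2 - np.einsum("mjt,mjs->ts", u_r, u_r,
                                                optimize=True)
    return neg2, gG, gRs, betas


# ---------------------------------------------------------------------------
# Parameterization and optimization
# ---------------------------------------------------------------------------

def _tril_pack(L, idx):
    return L[idx]


def _tril_unpack(x, T, idx):
    L = np.zeros((T, T))
    L[idx] = x
    return L


def _fit_core(preps, diag_G=False, start=None, maxiter=1000):
    """Shared-G REML fit over one or more prepared datasets.

    Returns (G, Rs, betas, loglik, converged, opt_result).
    """
    T = preps[0].T
    idx = np.tril_indices(T)
    n_tril = len(idx[0])
    diag_pos = np.where(idx[0] == idx[1])[0]

    G0 = np.mean([p.G0 for p in preps], axis=0)
    if start is not None:
        G0 = start[0]
    w, V = np.linalg.eigh((G0 + G0.T) / 2)
    LG0 = np.linalg.cholesky((V * np.clip(w, 1e-8, None)) @ V.T
                             + 1e-10 * np.eye(T))
    if diag_G:
        gpars0 = np.sqrt(np.clip(np.diag(G0), 1e-8, None))
        n_g = T
    else:
        gpars0 = _tril_pack(LG0, idx)
        n_g = n_tril

    rpars0 = []
    for d, p in enumerate(preps):
        R0 = p.R0 if start is None else start[1][d]
        LR = np.linalg.cholesky(R0)
        x = _tril_pack(LR, idx).copy()
        x[diag_pos] = np.log(x[diag_pos])
        rpars0.append(x)
    x0 = np.concatenate([gpars0] + rpars0)

    def unpack(x):
        g = x[:n_g]
        if diag_G:
            G = np.diag(g ** 2)
            LG = None
        else:
            LG = _tril_unpack(g, T, idx)
            G = LG @ LG.T
        Rs, LRs = [], []
        off = n_g
        for _ in preps:
            xr = x[off:off + n_tril].copy()
            off += n_tril
            LR = _tril_unpack(xr, T, idx)
            dg = np.exp(np.clip(xr[diag_pos], -40, 40))
            LR[np.diag_indices(T)] = dg
            Rs.append(LR @ LR.T)
            LRs.append(LR)
        return G, LG, g, Rs, LRs

    state = {}

    def objective(x):
        G, LG, g, Rs, LRs = unpack(x)
        try:
            neg2, gG, gRs, betas = _reml_components(preps, G, Rs)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(x)
        state["last"] = (G, Rs, betas, neg2)
        gG = (gG + gG.T) / 2
        if diag_G:
            grad_g = 2.0 * g * np.diag(gG)
        else:
            grad_g = _tril_pack(2.0 * (gG @ LG), idx)
        parts = [grad_g]
        for gR, LR in zip(gRs, LRs):
            gR = (gR + gR.T) / 2
            gL = 2.0 * (gR @ LR)
            gx = _tril_pack(gL, idx).copy()
            gx[diag_pos] *= np.diag(LR)
            parts.append(gx)
        return neg2, np.concatenate(parts)

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-11,
                                     "gtol": 1e-7})
    G, _, _, Rs, _ = unpack(res.x)
    neg2, _, _, betas = _reml_components(preps, G, Rs, want_grad=False)
    converged = bool(res.success) or np.linalg.norm(res.jac) < 1e-4
    return G, Rs, betas, -0.5 * neg2, converged, res


# ---------------------------------------------------------------------------
# Public fit containers
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    """Random-intercept fit of one trait: variance components and effects."""

    trait: str
    V_I: float
    V_R: float
    fixed_effects: dict
    reml_loglik: float
    converged: bool
    n_individuals: int
    n_obs: int


@dataclass
class MultivariateFit:
    """Multi-trait random-intercept fit: ID and R covariance matrices."""

    traits: list
    ID: np.ndarray
    R: np.ndarray
    beta: np.ndarray          # (p, T) per-trait fixed-effect columns
    fixed_names: list
    reml_loglik: float
    converged: bool
    n_individuals: int
    n_obs: int
    diagonal_id: bool = False
    _prep: _Prepared | None = field(default=None, repr=False, compare=False)

    def to_json(self, path):
        d = {
            "traits": list(self.traits),
            "ID": self.ID.tolist(),
            "R": self.R.tolist(),
            "beta": self.beta.tolist(),
            "fixed_names": list(self.fixed_names),
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_individuals": self.n_individuals,
            "n_obs": self.n_obs,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(traits=d["traits"], ID=np.array(d["ID"]), R=np.array(d["R"]),
                   beta=np.array(d["beta"]), fixed_names=d["fixed_names"],
                   reml_loglik=d["reml_loglik"], converged=d["converged"],
                   n_individuals=d["n_individuals"], n_obs=d["n_obs"])


@dataclass
class BootstrapEnsemble:
    """Parametric-bootstrap draws of an ID matrix for one species."""

    draws: np.ndarray         # (n_draws, T, T), each symmetric PSD
    seed: int
    method: str = "parametric"
    n_failed: int = 0

    @property
    def n_draws(self):
        return len(self.draws)

    def save(self, path):
        k, T, _ = self.draws.shape
        flat = self.draws.reshape(k, T * T)
        np.savetxt(path, flat, header=f"seed={self.seed} T={T} method={self.method}")

    @classmethod
    def point(cls, id_matrix):
        """Degenerate single-draw ensemble collapsing to a point estimate."""
        return cls(draws=np.asarray(id_matrix)[None, :, :], seed=0, method="point")


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def fit_multivariate(table: pd.DataFrame, traits=TRAITS,
                     constrain_diagonal: bool = False) -> MultivariateFit:
    """REML fit of the multi-trait random-intercept model for one species.

    With ``constrain_diagonal=True`` all ID covariances are fixed at zero
    (the reduced model of the 6-df covariance test); R stays unstructured.
    """
    prep = _prepare(table, traits)
    G, Rs, betas, ll, conv, _ = _fit_core([prep], diag_G=constrain_diagonal)
    beta = betas[0].reshape(prep.T, prep.p).T
    return MultivariateFit(traits=list(traits), ID=G, R=Rs[0], beta=beta,
                           fixed_names=prep.fixed_names, reml_loglik=ll,
                           converged=conv, n_individuals=prep.n_individuals,
                           n_obs=prep.n_obs, diagonal_id=constrain_diagonal,
                           _prep=prep)


def fit_univariate(table: pd.DataFrame, trait: str) -> UnivariateFit:
    """REML fit of the single-trait random-intercept model."""
    fit = fit_multivariate(table, traits=[trait])
    fx = dict(zip(fit.fixed_names, fit.beta[:, 0]))
    return UnivariateFit(trait=trait, V_I=float(fit.ID[0, 0]),
                         V_R=float(fit.R[0, 0]), fixed_effects=fx,
                         reml_loglik=fit.reml_loglik, converged=fit.converged,
                         n_individuals=fit.n_individuals, n_obs=fit.n_obs)


def fit_null_univariate(table: pd.DataFrame, trait: str) -> float:
    """REML log-likelihood of the no-individual-effect model (V_I = 0).

    Companion to :func:`fit_univariate` for the boundary likelihood-ratio
    test of repeatability.
    """
    prep = _prepare(table, [trait])
    # V_I fixed at zero: one-parameter optimization over log V_R.
    def neg2(logvr):
        G = np.zeros((1, 1))
        R = np.array([[np.exp(logvr[0])]])
        val, _, _, _ = _reml_components([prep], G, [R], want_grad=False)
        return val
    res = optimize.minimize_scalar(lambda v: neg2([v]),
                                   bounds=(-20, 20), method="bounded",
                                   options={"xatol": 1e-10})
    return -0.5 * res.fun


def repeatability(fit: UnivariateFit) -> float:
    """Intraclass correlation V_I / (V_I + V_R)."""
    tot = fit.V_I + fit.V_R
    if not tot > 0:
        raise ValueError("V_I + V_R must be positive")
    return fit.V_I / tot


def lrt_mixture_p(loglik_full: float, loglik_reduced: float, tol: float = 1e-6):
    """Boundary LRT for a single variance component.

    The statistic 2*(l_full - l_reduced) is referred to an equal mixture of a
    point mass at zero and chi-square with 1 df, so p = 0.5 * P(chi2_1 > stat)
    and p = 0.5 exactly at stat = 0.
    """
    stat = 2.0 * (loglik_full - loglik_reduced)
    if stat < -tol * max(1.0, abs(loglik_full)) - 1e-8:
        raise ValueError(f"full model log-likelihood below reduced ({stat=}); "
                         "check convergence order")
    stat = max(stat, 0.0)
    return stat, 0.5 * float(chi2.sf(stat, 1))


def lrt_id_covariances(full: MultivariateFit, diagonal: MultivariateFit):
    """6-df LRT of the ID covariance terms (full vs diagonal-ID model)."""
    if full.traits != diagonal.traits or full.n_obs != diagonal.n_obs:
        raise ValueError("fits must be on the same data and traits")
    T = len(full.traits)
    df = T * (T - 1) // 2
    stat = max(2.0 * (full.reml_loglik - diagonal.reml_loglik), 0.0)
    return stat, df, float(chi2.sf(stat, df))


def fit_pair_blocked(table_s1: pd.DataFrame, table_s2: pd.DataFrame,
                     traits=TRAITS, constrain_equal: bool = False) -> MultivariateFit:
    """Cross-species blocked fit used by the pairwise ID-equality test.

    No individual belongs to both species, so the unconstrained blocked
    likelihood separates into the two single-species fits; the constrained
    model shares one ID across species (10 common parameters for 4 traits)
    while residual covariances and fixed effects stay species-specific.
    Returns an 8-trait fit whose ID and R are block-diagonal.
    """
    shared = set(table_s1["fish_id"]) & set(table_s2["fish_id"])
    if shared:
        raise DesignError(f"individuals appear in both species: {sorted(shared)[:3]}")
    preps = [_prepare(table_s1, traits), _prepare(table_s2, traits)]
    T = preps[0].T
    if constrain_equal:
        G, Rs, betas, ll, conv, _ = _fit_core(preps)
        G1 = G2 = G
    else:
        f1 = fit_multivariate(table_s1, traits)
        f2 = fit_multivariate(table_s2, traits)
        G1, G2 = f1.ID, f2.ID
        Rs = [f1.R, f2.R]
        ll = f1.reml_loglik + f2.reml_loglik
        conv = f1.converged and f2.converged
        betas = [f1.beta.T.ravel(), f2.beta.T.ravel()]
    IDb = np.zeros((2 * T, 2 * T))
    Rb = np.zeros((2 * T, 2 * T))
    IDb[:T, :T], IDb[T:, T:] = G1, G2
    Rb[:T, :T], Rb[T:, T:] = Rs[0], Rs[1]
    labels = [f"s1_{t}" for t in traits] + [f"s2_{t}" for t in traits]
    p = preps[0].p
    beta = np.full((max(p, preps[1].p), 2 * T), np.nan)
    beta[:p, :T] = betas[0].reshape(T, p).T
    beta[:preps[1].p, T:] = betas[1].reshape(T, preps[1].p).T
    return MultivariateFit(traits=labels, ID=IDb, R=Rb, beta=beta,
                           fixed_names=preps[0].fixed_names,
                           reml_loglik=ll, converged=conv,
                           n_individuals=preps[0].n_individuals + preps[1].n_individuals,
                           n_obs=preps[0].n_obs + preps[1].n_obs)


def lrt_id_equality(unconstrained: MultivariateFit, constrained: MultivariateFit):
    """10-df LRT of ID_s1 = ID_s2 from the blocked pair fits."""
    if unconstrained.n_obs != constrained.n_obs:
        raise ValueError("fits must be on the same pooled data")
    T = len(unconstrained.traits) // 2
    df = T * (T + 1) // 2
    stat = max(2.0 * (unconstrained.reml_loglik - constrained.reml_loglik), 0.0)
    return stat, df, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def parametric_bootstrap(fit: MultivariateFit, table: pd.DataFrame = None,
                         n_draws: int = 200, seed: int = 0) -> BootstrapEnsemble:
    """Simulate-from-fit-and-refit bootstrap of the ID matrix.

    Each draw simulates a complete dataset from the fitted model on the
    original design (same individuals, trials, repeat and order covariates)
    and refits it; the refitted ID matrices form the ensemble.  Draws whose
    refit fails are excluded and counted.
    """
    prep = fit._prep
    if prep is None:
        if table is None:
            raise ValueError("fit carries no design; pass the trial table")
        prep = _prepare(table, fit.traits)
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    T = prep.T
    betaq = fit.beta.T.ravel()
    w, V = np.linalg.eigh(fit.ID)
    Lid = V * np.sqrt(np.clip(w, 0.0, None))
    Lr = np.linalg.cholesky(fit.R)
    mean_by_group = [Xs @ betaq for (_, Xs, _) in prep.groups]

    draws = []
    n_failed = 0
    start = (fit.ID, [fit.R])
    for _ in range(n_draws):
        ys_new = []
        for (n, Xs, _), mu in zip(prep.groups, mean_by_group):
            m = Xs.shape[0]
            u = rng.standard_normal((m, T)) @ Lid.T
            e = rng.standard_normal((m, n, T)) @ Lr.T
            y = mu.reshape(m, n, T) + u[:, None, :] + e
            ys_new.append(y.reshape(m, n * T))
        newprep = prep.with_response(ys_new)
        try:
            G, _, _, _, conv, _ = _fit_core([newprep], diag_G=fit.diagonal_id,
                                            start=start, maxiter=500)
            if not np.isfinite(G).all():
                raise FloatingPointError("non-finite estimate")
            draws.append(G)
        except (np.linalg.LinAlgError, FloatingPointError, DesignError):
            n_failed += 1
    if not draws:
        raise RuntimeError("all bootstrap refits failed")
    return BootstrapEnsemble(draws=np.array(draws), seed=seed,
                             n_failed=n_failed)
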