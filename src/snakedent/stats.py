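"""Phylogenetic comparative statistics.

Implements, from first principles, the comparative toolkit the dental
analyses rely on:

* Felsenstein's phylogenetic independent contrasts (PIC) and the
  through-origin contrast regression used to screen traits for cranium-size
  scaling;
* phylogenetic signal: Pagel's lambda by maximum likelihood with a
  likelihood-ratio test, and Blomberg's K with a tip-permutation test;
* phylogenetic GLS ("phyl.resid"-style residuals and PGLS regression);
* simulation-null phylogenetic ANOVA with Holm-corrected post-hoc pairwise
  tests;
* phylogenetic principal components analysis on the evolutionary
  (GLS) covariance or correlation matrix.

All operations take traits either as arrays aligned to the tree's
post-order tip order or as mappings/Series keyed by tip label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .tree import Phylogeny, PhyloCovariance, TreeError, lambda_transform, vcv_matrix

__all__ = [
    "pic",
    "pic_regression",
    "phylo_signal_lambda",
    "phylo_signal_K",
    "phylo_signal",
    "phyl_resid",
    "pgls",
    "phyl_anova",
    "ppca",
    "SignalResult",
    "PGLSResult",
    "ANOVAResult",
    "PPCAResult",
    "PICRegressionResult",
]


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------


def _align(species: Sequence[str], trait, name: str = "trait") -> np.ndarray:
    """Return trait values as a float array in the given species order."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, Mapping):
        missing = [s for s in species if s not in trait or pd.isna(trait[s])]
        if missing:
            raise ValueError(
                f"{name} missing for species: {', '.join(map(str, missing))}"
            )
        return np.array([float(trait[s]) for s in species])
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (len(species),):
        raise ValueError(
            f"{name} has length {arr.shape}, expected {len(species)} values "
            "in tree tip order"
        )
    if np.isnan(arr).any():
        bad = [species[i] for i in np.flatnonzero(np.isnan(arr))]
        raise ValueError(f"{name} missing for species: {', '.join(bad)}")
    return arr


def _chol(V: np.ndarray):
    try:
        return linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(f"singular phylogenetic covariance: {err}") from None


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------


def pic(tree: Phylogeny, trait) -> np.ndarray:
    """Standardized phylogenetic independent contrasts.

    Felsenstein pruning: at each internal node the contrast is
    ``(x_left - x_right) / sqrt(v_left + v_right)``; the node is assigned
    the variance-weighted average of its children and its parent branch is
    extended by ``v_l * v_r / (v_l + v_r)``.  Returns the ``n - 1``
    contrasts in post-order internal-node order.  Requires a strictly
    bifurcating tree.
    """
    if any(len(n.children) > 2 for n in tree.postorder() if not n.is_leaf):
        raise TreeError("PIC requires a fully bifurcating tree (polytomy found)")
    x = _align(tree.tip_labels, trait)
    values = dict(zip(tree.tip_labels, x))
    state: dict = {}
    contrasts: list[float] = []
    for node in tree.postorder():
        if node.is_leaf:
            state[node] = (values[node.label], float(node.length))
        elif len(node.children) == 1:
            # degree-1 node (e.g. the retained root of a pruned tree):
            # pass the child through, extending its branch variance
            xc, vc = state[node.children[0]]
            state[node] = (xc, vc + (node.length or 0.0))
        else:
            (x1, v1), (x2, v2) = (state[c] for c in node.children)
            if v1 + v2 <= 0:
                raise TreeError("zero total branch length at an internal node")
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            xv = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 else (
                x1 if v1 == 0 else x2
            )
            vv = (node.length or 0.0) + v1 * v2 / (v1 + v2)
            state[node] = (xv, vv)
    return np.asarray(contrasts)


@dataclass
class PICRegressionResult:
    """Through-origin OLS of one contrast set on another."""

    slope: float
    F: float
    df: tuple[int, int]
    r_squared: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "F": self.F,
            "df1": self.df[0],
            "df2": self.df[1],
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


def pic_regression(cx: np.ndarray, cy: np.ndarray) -> PICRegressionResult:
    """No-intercept regression of contrasts ``cy`` on ``cx``.

    Contrasts have expectation zero under Brownian motion, so the
    regression is forced through the origin.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    if cx.shape != cy.shape or cx.ndim != 1:
        raise ValueError("contrast vectors must be 1-D and of equal length")
    sxx = float(cx @ cx)
    if sxx == 0:
        raise ValueError("all contrasts of the predictor are zero")
    slope = float(cx @ cy) / sxx
    resid = cy - slope * cx
    rss = float(resid @ resid)
    syy = float(cy @ cy)
    m = cx.size
    df2 = m - 1
    if rss == 0:
        F, p = np.inf, 0.0
    else:
        F = (syy - rss) / (rss / df2)
        p = float(sps.f.sf(F, 1, df2))
    r2 = 1.0 - rss / syy if syy > 0 else np.nan
    return PICRegressionResult(slope=slope, F=float(F), df=(1, df2), r_squared=r2, p_value=p)


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


@dataclass
class SignalResult:
    """Phylogenetic signal of one trait (Pagel's lambda and/or Blomberg's K)."""

    trait: str
    lam: float | None = None
    log_likelihood: float | None = None
    log_likelihood_lambda0: float | None = None
    p_lambda: float | None = None
    K: float | None = None
    p_K: float | None = None
    n_permutations: int | None = None

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "lambda": self.lam,
            "logL": self.log_likelihood,
            "logL_lambda0": self.log_likelihood_lambda0,
            "p_lambda": self.p_lambda,
            "K": self.K,
            "p_K": self.p_K,
            "n_permutations": self.n_permutations,
        }


def _lambda_profile_loglik(lam: float, x: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of lambda (mean and rate maximized out)."""
    n = x.size
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    cho = _chol(V)
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cho, one)
    Vix = linalg.cho_solve(cho, x)
    mu = (one @ Vix) / (one @ Vi1)
    r = x - mu
    Vir = Vix - mu * Vi1
    s2 = float(r @ Vir) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def phylo_signal_lambda(tree: Phylogeny, trait, trait_name: str = "trait") -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    The likelihood is maximized over lambda in [0, 1] (profiling out the
    phylogenetic mean and Brownian rate); the p-value is a likelihood-ratio
    chi-square(1) test against lambda = 0 (no signal).
    """
    x = _align(tree.tip_labels, trait, trait_name)
    if x.size < 4:
        raise ValueError("lambda estimation needs at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across tips")
    C = vcv_matrix(tree).matrix

    def nll(lam: float) -> float:
        return -_lambda_profile_loglik(lam, x, C)

    # deterministic coarse grid, then bounded local refinement
    grid = np.linspace(0.0, 1.0, 101)
    grid_vals = np.array([nll(g) for g in grid])
    best = grid[int(np.argmin(grid_vals))]
    lo, hi = max(0.0, best - 0.02), min(1.0, best + 0.02)
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    lam_hat, logL = (
        (float(res.x), -float(res.fun))
        if res.fun <= grid_vals.min()
        else (float(best), -float(grid_vals.min()))
    )
    logL0 = _lambda_profile_loglik(0.0, x, C)
    lr = max(0.0, 2.0 * (logL - logL0))
    p = float(sps.chi2.sf(lr, 1))
    return SignalResult(
        trait=trait_name,
        lam=lam_hat,
        log_likelihood=logL,
        log_likelihood_lambda0=logL0,
        p_lambda=p,
    )


def _k_statistics(X: np.ndarray, C: np.ndarray, cho) -> np.ndarray:
    """Blomberg's K for each column of X given covariance C."""
    n = C.shape[0]
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cho, one)
    s = float(one @ Ci1)
    a = (Ci1 @ X) / s  # phylogenetic mean per column
    R = X - a
    CiR = linalg.cho_solve(cho, R)
    num = np.einsum("ij,ij->j", R, R)
    den = np.einsum("ij,ij->j", R, CiR)
    expected = (np.trace(C) - n / s) / (n - 1)
    return (num / den) / expected


def phylo_signal_K(
    tree: Phylogeny,
    trait,
    nperm: int = 999,
    seed: int | None = None,
    trait_name: str = "trait",
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K is the observed ratio of among-tip to phylogenetically corrected
    mean squares over its Brownian-motion expectation on the same tree
    (K = 1 under Brownian motion).  The p-value counts permutations with
    K at least as large as observed, with the (b + 1) / (nperm + 1) rule.
    """
    x = _align(tree.tip_labels, trait, trait_name)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across tips")
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    C = vcv_matrix(tree).matrix
    cho = _chol(C)
    k_obs = float(_k_statistics(x[:, None], C, cho)[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((x.size, nperm))
    for j in range(nperm):
        perms[:, j] = rng.permutation(x)
    k_null = _k_statistics(perms, C, cho)
    p = (np.count_nonzero(k_null >= k_obs) + 1) / (nperm + 1)
    return SignalResult(trait=trait_name, K=k_obs, p_K=float(p), n_permutations=nperm)


def phylo_signal(
    tree: Phylogeny,
    trait,
    nperm: int = 999,
    seed: int | None = None,
    trait_name: str = "trait",
) -> SignalResult:
    """Combined lambda + K signal test for one trait."""
    lam_res = phylo_signal_lambda(tree, trait, trait_name=trait_name)
    k_res = phylo_signal_K(tree, trait, nperm=nperm, seed=seed, trait_name=trait_name)
    lam_res.K = k_res.K
    lam_res.p_K = k_res.p_K
    lam_res.n_permutations = k_res.n_permutations
    return lam_res


# ---------------------------------------------------------------------------
# GLS: phylogenetic residuals and PGLS
# ---------------------------------------------------------------------------


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS fit: returns (beta, residuals, rss, tss, cho)."""
    cho = _chol(V)
    ViX = linalg.cho_solve(cho, X)
    XtViX = X.T @ ViX
    try:
        beta = linalg.solve(XtViX, ViX.T @ y, assume_a="pos")
    except linalg.LinAlgError:
        raise ValueError("singular design matrix") from None
    resid = y - X @ beta
    Vir = linalg.cho_solve(cho, resid)
    rss = float(resid @ Vir)
    one = np.ones_like(y)
    Vi1 = linalg.cho_solve(cho, one)
    Viy = linalg.cho_solve(cho, y)
    b0 = (one @ Viy) / (one @ Vi1)
    r0 = y - b0
    tss = float(r0 @ (Viy - b0 * Vi1))
    return beta, resid, rss, tss, cho


def phyl_resid(tree: Phylogeny, y, x, C: PhyloCovariance | None = None) -> pd.Series:
    """Residuals from a phylogenetic (GLS) regression of y on x.

    beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept; residuals
    y - X beta are the size-corrected trait values used downstream.
    """
    species = tree.tip_labels
    yv = _align(species, y, "y")
    xv = _align(species, x, "x")
    V = (C or vcv_matrix(tree)).matrix
    X = np.column_stack([np.ones_like(xv), xv])
    if np.ptp(xv) == 0:
        raise ValueError("singular design matrix (constant predictor)")
    beta, resid, _, _, _ = _gls(X, yv, V)
    return pd.Series(resid, index=species, name="residual")


@dataclass
class PGLSResult:
    """Phylogenetic generalized least-squares regression of y on x."""

    response: str
    predictor: str
    intercept: float
    slope: float
    F: float
    df: tuple[int, int]
    r_squared: float
    p_value: float
    lambda_mode: str
    lam: float
    residuals: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "intercept": self.intercept,
            "slope": self.slope,
            "F": self.F,
            "df1": self.df[0],
            "df2": self.df[1],
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "lambda_mode": self.lambda_mode,
            "lambda": self.lam,
        }


def pgls(
    tree: Phylogeny,
    y,
    x,
    lambda_mode: str = "fixed1",
    response: str = "y",
    predictor: str = "x",
) -> PGLSResult:
    """PGLS regression under a lambda-scaled Brownian covariance.

    ``lambda_mode="fixed1"`` (default) conditions on the untransformed
    Brownian covariance; ``"ML"`` profiles lambda out by maximum
    likelihood under the regression model.
    """
    species = tree.tip_labels
    yv = _align(species, y, response)
    xv = _align(species, x, predictor)
    n = yv.size
    if n < 4:
        raise ValueError("PGLS needs at least 4 tips")
    C = vcv_matrix(tree).matrix
    X = np.column_stack([np.ones(n), xv])

    if lambda_mode == "fixed1":
        lam = 1.0
    elif lambda_mode == "ML":

        def nll(l: float) -> float:
            V = C * l
            np.fill_diagonal(V, np.diag(C))
            cho = _chol(V)
            ViX = linalg.cho_solve(cho, X)
            beta = linalg.solve(X.T @ ViX, ViX.T @ yv, assume_a="pos")
            r = yv - X @ beta
            s2 = float(r @ linalg.cho_solve(cho, r)) / n
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

        grid = np.linspace(0.0, 1.0, 101)
        vals = [nll(g) for g in grid]
        best = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            nll,
            bounds=(max(0.0, best - 0.02), min(1.0, best + 0.02)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x) if res.fun <= min(vals) else float(best)
    else:
        raise ValueError("lambda_mode must be 'fixed1' or 'ML'")

    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    beta, resid, rss, tss, _ = _gls(X, yv, V)
    df2 = n - 2
    if rss <= 1e-12 * max(tss, 1.0):
        F, p, r2 = np.inf, 0.0, 1.0
    else:
        F = (tss - rss) / (rss / df2)
        p = float(sps.f.sf(F, 1, df2))
        r2 = 1.0 - rss / tss
    return PGLSResult(
        response=response,
        predictor=predictor,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        F=float(F),
        df=(1, df2),
        r_squared=float(r2),
        p_value=p,
        lambda_mode=lambda_mode,
        lam=lam,
        residuals=pd.Series(resid, index=species, name="residual"),
    )


# ---------------------------------------------------------------------------
# simulation-null phylogenetic ANOVA
# ---------------------------------------------------------------------------


def _anova_F(X: np.ndarray, gidx: list[np.ndarray]) -> np.ndarray:
    """Classical one-way ANOVA F for each column of X given group indices."""
    n = X.shape[0]
    k = len(gidx)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for idx in gidx:
        gm = X[idx].mean(axis=0)
        ssb += idx.size * (gm - grand) ** 2
        ssw += ((X[idx] - gm) ** 2).sum(axis=0)
    return (ssb / (k - 1)) / (ssw / (n - k))


def _pairwise_t(X: np.ndarray, gidx: list[np.ndarray]) -> np.ndarray:
    """Pairwise pooled-variance t statistics, shape (npairs, ncols)."""
    n = X.shape[0]
    k = len(gidx)
    means = np.stack([X[idx].mean(axis=0) for idx in gidx])
    ssw = np.zeros(X.shape[1])
    for idx, gm in zip(gidx, means):
        ssw += ((X[idx] - gm) ** 2).sum(axis=0)
    mse = ssw / (n - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1.0 / gidx[i].size + 1.0 / gidx[j].size))
            rows.append((means[i] - means[j]) / se)
    return np.stack(rows)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class ANOVAResult:
    """Simulation-null phylogenetic ANOVA of a trait across groups."""

    grouping: str
    group_means: dict[str, float]
    F: float
    p_value: float
    n_simulations: int
    seed: int | None
    posthoc_t: pd.DataFrame | None = None
    posthoc_p: pd.DataFrame | None = None
    correction: str = "holm"

    def to_dict(self) -> dict:
        d = {
            "grouping": self.grouping,
            "group_means": self.group_means,
            "F": self.F,
            "p_value": self.p_value,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "correction": self.correction,
        }
        if self.posthoc_t is not None:
            d["posthoc_t"] = self.posthoc_t.to_dict()
            d["posthoc_p"] = self.posthoc_p.to_dict()
        return d


def phyl_anova(
    tree: Phylogeny,
    trait,
    groups,
    nsim: int = 1000,
    posthoc: bool = True,
    seed: int | None = None,
    grouping: str = "group",
) -> ANOVAResult:
    """Phylogenetic ANOVA with a Brownian-motion simulation null.

    The classical one-way F is computed on the data; its null distribution
    comes from ``nsim`` Brownian simulations on the tree with the rate
    estimated from the observed trait (mean squared standardized contrast
    on bifurcating trees, GLS quadratic form otherwise).  The p-value uses
    the add-one rule (count of null F >= observed + 1) / (nsim + 1).
    Post-hoc pairwise t statistics get simulation-based p-values corrected
    by Holm's method.
    """
    species = tree.tip_labels
    x = _align(species, trait)
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    if isinstance(groups, Mapping):
        glabels = [groups[s] for s in species]
    else:
        glabels = list(groups)
        if len(glabels) != len(species):
            raise ValueError("groups length does not match number of tips")
    if nsim < 100:
        raise ValueError("nsim must be at least 100")
    levels = sorted(set(map(str, glabels)))
    glabels = [str(g) for g in glabels]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    gidx = [np.flatnonzero(np.array(glabels) == lev) for lev in levels]
    for lev, idx in zip(levels, gidx):
        if idx.size < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 members")

    F_obs = float(_anova_F(x[:, None], gidx)[0])
    C = vcv_matrix(tree).matrix
    try:
        rate = float(np.mean(pic(tree, x) ** 2))
    except TreeError:  # polytomies: GLS quadratic-form rate estimator
        cho = _chol(C)
        one = np.ones_like(x)
        Ci1 = linalg.cho_solve(cho, one)
        a = float(one @ linalg.cho_solve(cho, x)) / float(one @ Ci1)
        r = x - a
        rate = float(r @ linalg.cho_solve(cho, r)) / (x.size - 1)

    rng = np.random.default_rng(seed)
    L = linalg.cholesky(C, lower=True)
    sims = np.sqrt(rate) * (L @ rng.standard_normal((x.size, nsim)))
    F_null = _anova_F(sims, gidx)
    p = (np.count_nonzero(F_null >= F_obs) + 1) / (nsim + 1)

    means = {lev: float(x[idx].mean()) for lev, idx in zip(levels, gidx)}

    t_df = p_df = None
    if posthoc:
        t_obs = _pairwise_t(x[:, None], gidx)[:, 0]
        t_null = _pairwise_t(sims, gidx)
        exceed = (np.abs(t_null) >= np.abs(t_obs)[:, None]).sum(axis=1)
        p_raw = (exceed + 1) / (nsim + 1)
        p_adj = _holm(p_raw)
        k = len(levels)
        tm = np.zeros((k, k))
        pm = np.ones((k, k))
        pos = 0
        for i in range(k):
            for j in range(i + 1, k):
                tm[i, j], tm[j, i] = t_obs[pos], -t_obs[pos]
                pm[i, j] = pm[j, i] = p_adj[pos]
                pos += 1
        t_df = pd.DataFrame(tm, index=levels, columns=levels)
        p_df = pd.DataFrame(pm, index=levels, columns=levels)

    return ANOVAResult(
        grouping=grouping,
        group_means=means,
        F=F_obs,
        p_value=float(p),
        n_simulations=nsim,
        seed=seed,
        posthoc_t=t_df,
        posthoc_p=p_df,
    )


# ---------------------------------------------------------------------------
# phylogenetic PCA
# ---------------------------------------------------------------------------


@dataclass
class PPCAResult:
    """Phylogenetic PCA on the evolutionary covariance/correlation matrix."""

    trait_names: list[str]
    mean: np.ndarray
    R: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mode: str

    def to_dict(self) -> dict:
        return {
            "trait_names": self.trait_names,
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.to_dict(),
            "mode": self.mode,
        }


def ppca(tree: Phylogeny, traits: pd.DataFrame, mode: str = "covariance") -> PPCAResult:
    """Phylogenetic principal components analysis.

    The evolutionary mean ``a = (1'C^-1 1)^-1 1'C^-1 X`` and evolutionary
    covariance ``R = (X - 1a)' C^-1 (X - 1a) / (n - 1)`` are computed
    under the Brownian covariance C; R (correlation-rescaled when
    ``mode="correlation"``) is eigendecomposed, scores are the centered
    (and, for correlation mode, standardized) data rotated onto the
    eigenvectors, and the reported loadings are Pearson correlations
    between scores and the raw traits (the display convention of the
    field's standard implementation).
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    species = tree.tip_labels
    if not isinstance(traits, pd.DataFrame):
        raise TypeError("traits must be a DataFrame indexed by species")
    missing = [s for s in species if s not in traits.index]
    if missing:
        raise ValueError(f"traits missing for species: {', '.join(missing)}")
    X = traits.loc[species].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait matrix contains missing values")
    n, m = X.shape
    if m < 1:
        raise ValueError("need at least 1 trait")
    C = vcv_matrix(tree).matrix
    cho = _chol(C)
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cho, one)
    a = (Ci1 @ X) / float(one @ Ci1)
    Xc = X - a
    R_cov = (Xc.T @ linalg.cho_solve(cho, Xc)) / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R_cov))
        if np.any(d == 0):
            raise ValueError("constant trait under correlation mode")
        R = R_cov / np.outer(d, d)
        Xr = Xc / d
    else:
        R = R_cov
        Xr = Xc
    evals, evecs = linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals < -1e-10):
        warnings.warn("rank-deficient trait matrix: negative eigenvalues clipped to 0")
    evals = np.clip(evals, 0.0, None)
    # deterministic sign convention: largest-magnitude element positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xr @ evecs
    pc_names = [f"PC{i + 1}" for i in range(m)]
    load = np.full((m, m), np.nan)
    for j in range(m):
        sj = scores[:, j]
        if sj.std() > 0:
            for t in range(m):
                if X[:, t].std() > 0:
                    load[t, j] = np.corrcoef(sj, X[:, t])[0, 1]
    return PPCAResult(
        trait_names=list(traits.columns),
        mean=a,
        R=R,
        eigenvalues=evals,
        eigenvectors=evecs,
        loadings=pd.DataFrame(load, index=traits.columns, columns=pc_names),
        scores=pd.DataFrame(scores, index=species, columns=pc_names),
        mode=mode,
    )
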