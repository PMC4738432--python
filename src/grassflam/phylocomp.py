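"""Phylogenetic comparative statistics.

* lambda-scaled Brownian covariance matrices from a dated tree
* PGLS: generalized least squares with phylogenetic covariance, with the
  signal parameter lambda either fixed or profiled by maximum likelihood
* Pagel's lambda estimation with likelihood-ratio tests against the
  no-signal (lambda = 0) and pure-Brownian (lambda = 1) boundaries
* a bivariate Gaussian mixed model (Gibbs sampler, inverse-Wishart priors)
  for two traits measured on individuals nested in species, with
  phylogenetically structured species effects; the species-level and
  residual covariances yield across-species and within-species regression
  slopes and their HPD intervals.

Under the lambda transform the off-diagonal entries of the Brownian
covariance are multiplied by lambda in [0, 1] while tip variances are kept,
interpolating between a star phylogeny (no signal) and pure Brownian motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)


# ----------------------------------------------------------- covariance

def brownian_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian trait covariance: V[i, j] = depth of the MRCA of tips i, j.

    Computed from root-to-tip depths and patristic distances via
    depth(mrca) = (d_root_i + d_root_j - d_ij) / 2.
    """
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: str(t.label))
    labels = [str(t.label).strip() for t in taxa]
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon] = leaf.distance_from_root()
    n = len(taxa)
    v = np.empty((n, n))
    for i, ti in enumerate(taxa):
        v[i, i] = depths[ti]
        for j in range(i + 1, n):
            tj = taxa[j]
            d = pdm.patristic_distance(ti, tj)
            v[i, j] = v[j, i] = 0.5 * (depths[ti] + depths[tj] - d)
    off = ~np.eye(n, dtype=bool)
    v[off & (np.abs(v) < 1e-12)] = 0.0        # clamp float dust on disjoint clades
    return labels, v


def lambda_transform(v: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keeping tip variances."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * v
    np.fill_diagonal(out, np.diag(v))
    return out


def phylo_covariance(tree: dendropy.Tree, lam: float = 1.0) -> tuple[list[str], np.ndarray]:
    """Lambda-scaled phylogenetic covariance matrix and its species order."""
    labels, v = brownian_covariance(tree)
    return labels, lambda_transform(v, lam)


# ------------------------------------------------------------------ PGLS

@dataclass
class PglsFit:
    coef: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma2: float
    lam: float
    loglik: float
    r_squared: float
    names: list


def _gls(y: np.ndarray, x: np.ndarray, v: np.ndarray):
    """GLS via Cholesky whitening; returns (beta, sigma2_ml, loglik, xtvx_inv, rss_w)."""
    n = y.size
    try:
        chol = linalg.cholesky(v, lower=True)
    except np.linalg.LinAlgError:
        # near-zero terminal branches can make V numerically singular
        chol = linalg.cholesky(v + 1e-10 * float(np.mean(np.diag(v))) * np.eye(n), lower=True)
    yw = linalg.solve_triangular(chol, y, lower=True)
    xw = linalg.solve_triangular(chol, x, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear columns)")
    resid_w = yw - xw @ beta
    rss_w = float(resid_w @ resid_w)
    sigma2 = rss_w / n
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(chol))))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
    xtvx_inv = np.linalg.inv(xw.T @ xw)
    return beta, sigma2, loglik, xtvx_inv, rss_w


def pgls_fit(y: np.ndarray, x: np.ndarray, v: np.ndarray,
             lam: "float | str" = 1.0, names: Optional[list] = None) -> PglsFit:
    """Phylogenetic GLS of y on design X under covariance sigma^2 V(lambda).

    ``lam`` is a fixed value in [0, 1] or ``"ml"`` to profile it by maximum
    likelihood.  With lambda = 0 the fit reduces to ordinary least squares.
    Wald 95% CIs use the unbiased sigma^2 estimate and a t reference.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n, p = x.shape

    if lam == "ml":
        res = optimize.minimize_scalar(
            lambda l: -_gls(y, x, lambda_transform(v, l))[2],
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_candidates = [float(res.x), 0.0, 1.0]
        lam = max(lam_candidates, key=lambda l: _gls(y, x, lambda_transform(v, l))[2])

    vl = lambda_transform(v, float(lam))
    beta, sigma2, loglik, xtvx_inv, rss_w = _gls(y, x, vl)
    sigma2_ub = rss_w / max(n - p, 1)
    se = np.sqrt(sigma2_ub * np.diag(xtvx_inv))
    tcrit = stats.t.ppf(0.975, max(n - p, 1))

    # R^2 analog: 1 - RSS_w / TSS_w against the GLS intercept-only model
    ones = np.ones((n, 1))
    _, _, _, _, tss_w = _gls(y, ones, vl)
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else np.nan
    return PglsFit(
        coef=beta, se=se, ci_lower=beta - tcrit * se, ci_upper=beta + tcrit * se,
        sigma2=sigma2, lam=float(lam), loglik=loglik, r_squared=r2,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )


# --------------------------------------------------------- Pagel's lambda

@dataclass
class LambdaSignal:
    lambda_ml: float
    loglik_ml: float
    loglik_0: float
    loglik_1: float
    p_vs_0: float
    p_vs_1: float
    flat_likelihood: bool = False


def estimate_lambda(y: np.ndarray, v: np.ndarray, x: Optional[np.ndarray] = None) -> LambdaSignal:
    """Maximum-likelihood Pagel's lambda with boundary likelihood-ratio tests.

    The profile likelihood is maximized over [0, 1] by bounded 1-D
    optimization (endpoints always evaluated).  LRTs against lambda = 0 and
    lambda = 1 use a one-sided chi^2(1) reference with the boundary halving
    p = 0.5 * P(chi2_1 > LR); a star tree (all shared branch lengths zero)
    makes lambda non-identifiable and is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.ones((n, 1)) if x is None else np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != n:
        x = x.T

    off = v[~np.eye(n, dtype=bool)]
    flat = bool(np.allclose(off, 0.0))

    def nll(lam):
        return -_gls(y, x, lambda_transform(v, lam))[2]

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [float(res.x), 0.0, 1.0]
    lam_ml = max(candidates, key=lambda l: -nll(l))
    ll_ml = -nll(lam_ml)
    ll0, ll1 = -nll(0.0), -nll(1.0)

    def boundary_p(ll_restricted):
        lr = max(0.0, 2.0 * (ll_ml - ll_restricted))
        return 1.0 if lr <= 0 else float(0.5 * stats.chi2.sf(lr, df=1))

    if flat:
        logger.warning("estimate_lambda: star tree, lambda not identifiable")
    return LambdaSignal(lam_ml, ll_ml, ll0, ll1, boundary_p(ll0), boundary_p(ll1), flat)


# -------------------------------------------- bivariate phylogenetic GLMM

def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(d[0]), float(d[-1])
    widths = d[k:] - d[: n - k]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + k])


def effective_size(draws: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    d = np.asarray(draws, dtype=float)
    n = d.size
    d = d - d.mean()
    var = float(d @ d) / n
    if var == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 2):
        rho = float(d[:-lag] @ d[lag:]) / (n * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    return n / (1.0 + 2.0 * acf_sum)


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of one chain (halves treated as two chains)."""
    d = np.asarray(draws, dtype=float)
    half = d.size // 2
    chains = np.stack([d[:half], d[half: 2 * half]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


@dataclass
class BivariatePosterior:
    sigma_sp_draws: np.ndarray        # (n_draws, 2, 2) species-level covariance
    sigma_res_draws: np.ndarray       # (n_draws, 2, 2) residual covariance
    b_within_draws: np.ndarray
    b_across_draws: np.ndarray
    b_within_mean: float
    b_across_mean: float
    b_within_hpd: tuple
    b_across_hpd: tuple
    delta_b_mean: float
    delta_b_hpd: tuple
    ess_within: float
    ess_across: float
    rhat_within: float
    rhat_across: float
    n_rejected: int


def bivariate_mixed_model(
    x: np.ndarray,
    y: np.ndarray,
    species: Sequence[str],
    species_order: Sequence[str],
    a_matrix: np.ndarray,
    iterations: int = 50_000,
    burnin: int = 1_000,
    thin: int = 50,
    prior_nu: float = 0.002,
    prior_v: float = 1.0,
    seed: int = 0,
) -> BivariatePosterior:
    """Gibbs sampler for a bivariate Gaussian mixed model with species effects.

    Model: (x_ij, y_ij) = mu + u_s + e_ij with species effects
    vec(U) ~ N(0, Sigma_sp (x) A) — A the (Brownian or lambda-scaled)
    phylogenetic covariance over ``species_order`` — and iid residuals
    e_ij ~ N(0, Sigma_res).  Both covariances carry weakly-informative
    inverse-Wishart priors with scale ``prior_nu * prior_v * I`` and
    ``prior_nu`` degrees of freedom.  All full conditionals are conjugate.

    The derived slopes are b_within = Sigma_res[x, y] / Sigma_res[x, x]
    (the pooled within-species regression of y on x) and
    b_across = Sigma_sp[x, y] / Sigma_sp[x, x] (the regression across
    species-level effects); HPDs are shortest 95% intervals.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.column_stack([x, y])                      # (N, 2)
    species = np.asarray(species)
    sp_index = {s: i for i, s in enumerate(species_order)}
    idx = np.array([sp_index[s] for s in species])
    n_sp = len(species_order)
    n_obs = z.shape[0]
    counts = np.bincount(idx, minlength=n_sp).astype(float)
    if np.any(counts == 0):
        raise ValueError("every species in species_order needs at least one record")

    a = np.asarray(a_matrix, dtype=float)
    a_inv = np.linalg.inv(a + 1e-12 * np.eye(n_sp))
    s0 = prior_nu * prior_v * np.eye(2)

    # state
    mu = z.mean(axis=0)
    u = np.zeros((n_sp, 2))
    sigma_res = np.cov(z.T) + 1e-6 * np.eye(2)
    sigma_sp = np.cov(z.T) / 2 + 1e-6 * np.eye(2)

    keep = []
    n_rejected = 0
    sums = np.zeros((n_sp, 2))

    for it in range(iterations):
        # --- species effects U | rest
        resid = z - mu
        sums.fill(0.0)
        np.add.at(sums, idx, resid)                  # (n_sp, 2) per-species sums
        sres_inv = np.linalg.inv(sigma_res)
        ssp_inv = np.linalg.inv(sigma_sp)
        prec = np.kron(ssp_inv, a_inv) + np.kron(sres_inv, np.diag(counts))
        b_vec = (sums @ sres_inv).T.reshape(-1)      # vec col-major over (species, trait)
        chol = np.linalg.cholesky(prec)
        mean_vec = np.linalg.solve(prec, b_vec)
        z_draw = rng.standard_normal(2 * n_sp)
        u_vec = mean_vec + linalg.solve_triangular(chol.T, z_draw, lower=False)
        u = u_vec.reshape(2, n_sp).T

        # --- grand mean mu | rest
        resid_mu = z - u[idx]
        mu_mean = resid_mu.mean(axis=0)
        mu_cov = sigma_res / n_obs
        mu = rng.multivariate_normal(mu_mean, mu_cov)

        # --- residual covariance | rest
        e = z - mu - u[idx]
        scale_res = s0 + e.T @ e
        sigma_res = stats.invwishart.rvs(df=prior_nu + n_obs, scale=scale_res, random_state=rng)

        # --- species covariance | rest
        scale_sp = s0 + u.T @ a_inv @ u
        sigma_sp = stats.invwishart.rvs(df=prior_nu + n_sp, scale=scale_sp, random_state=rng)

        for m in (sigma_res, sigma_sp):
            if np.linalg.det(m) <= 0:
                n_rejected += 1
                m += 1e-8 * np.eye(2)

        if it >= burnin and (it - burnin) % thin == 0:
            keep.append((sigma_sp.copy(), sigma_res.copy()))

    sp_draws = np.array([k[0] for k in keep])
    res_draws = np.array([k[1] for k in keep])
    b_within = res_draws[:, 0, 1] / res_draws[:, 0, 0]
    b_across = sp_draws[:, 0, 1] / sp_draws[:, 0, 0]
    delta = b_across - b_within

    rhat_w, rhat_a = split_rhat(b_within), split_rhat(b_across)
    if max(rhat_w, rhat_a) > 1.1:
        logger.warning("bivariate_mixed_model: split-Rhat %.3f > 1.1", max(rhat_w, rhat_a))

    return BivariatePosterior(
        sigma_sp_draws=sp_draws,
        sigma_res_draws=res_draws,
        b_within_draws=b_within,
        b_across_draws=b_across,
        b_within_mean=float(b_within.mean()),
        b_across_mean=float(b_across.mean()),
        b_within_hpd=hpd_interval(b_within),
        b_across_hpd=hpd_interval(b_across),
        delta_b_mean=float(delta.mean()),
        delta_b_hpd=hpd_interval(delta),
        ess_within=effective_size(b_within),
        ess_across=effective_size(b_across),
        rhat_within=rhat_w,
        rhat_across=rhat_a,
        n_rejected=n_rejected,
    )
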