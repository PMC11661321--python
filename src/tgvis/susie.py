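"""Sum-of-single-effects (SuSiE) regression on summary statistics.

This is the selection engine used throughout the package: stage-1
fine-mapping of per-pair xQTL effects and stage-2 joint selection of causal
gene-tissue pairs and direct causal variants both call :func:`susie_rss`.

The model is the standard z-score formulation: given a vector of marginal
z-scores ``z`` and the correlation matrix ``corr`` of the underlying
predictors, the joint effect ``b`` (on the z-coefficient scale) satisfies

    z ~ N(corr @ b, corr),      b = sum_l  b_l,

where each single effect ``b_l`` has exactly one nonzero coordinate with a
N(0, V_l) slab prior.  Fitting is by iterative Bayesian stepwise selection
(IBSS): each single effect is updated in turn against the residual z-scores,
with the per-effect prior variance V_l refined by an empirical-Bayes (EM)
step.  Convergence is monitored through the mean-field variational
objective.  The fit is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SusieFit",
    "CredibleSet",
    "susie_rss",
    "credible_sets",
    "estimate_prior_variance",
]

# Effects whose empirical-Bayes prior variance collapses below this value are
# treated as empty: they contribute nothing to PIPs and report no credible set.
PRIOR_VARIANCE_FLOOR = 1e-9


@dataclass
class CredibleSet:
    """A level-``coverage`` credible set for one single effect.

    members are sorted by descending posterior weight (ties broken by index);
    ``cumulative_pip`` is the posterior mass captured by the members within
    the effect; ``purity`` is the minimum absolute pairwise correlation among
    members (1.0 for singletons).
    """

    members: list[int]
    cumulative_pip: float
    purity: float
    effect_index: int


@dataclass
class SusieFit:
    L: int
    alpha: np.ndarray          # (L, p) posterior inclusion weights
    mu: np.ndarray             # (L, p) posterior means given inclusion
    mu2: np.ndarray            # (L, p) posterior second moments given inclusion
    prior_variance: np.ndarray  # (L,) per-effect slab variances after EB updates
    pip: np.ndarray            # (p,)
    credible_sets: list[CredibleSet]
    converged: bool
    elbo_trace: np.ndarray
    n_iter: int

    @property
    def active_effects(self) -> np.ndarray:
        """Indices of effects that were not pruned to the null."""
        return np.flatnonzero(self.prior_variance > PRIOR_VARIANCE_FLOOR)

    def posterior_mean(self) -> np.ndarray:
        """Marginal posterior mean coefficient, summed over active effects."""
        act = self.active_effects
        if act.size == 0:
            return np.zeros(self.alpha.shape[1])
        return (self.alpha[act] * self.mu[act]).sum(axis=0)

    def sample_coefficients(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one joint coefficient vector from the variational posterior.

        Each active effect independently samples its nonzero coordinate from
        alpha and an effect size from the conditional normal slab.
        """
        return self.sample_coefficient_means(rng, 1)

    def sample_coefficient_means(self, rng: np.random.Generator,
                                 n: int) -> np.ndarray:
        """Mean of ``n`` posterior coefficient draws (inverse-CDF sampling
        of the inclusion index per effect, then the conditional slab)."""
        p = self.alpha.shape[1]
        out = np.zeros(p)
        for l in self.active_effects:
            cum = np.cumsum(self.alpha[l])
            cum[-1] = 1.0
            js = np.searchsorted(cum, rng.random(n))
            sd = np.sqrt(np.maximum(self.mu2[l] - self.mu[l] ** 2, 0.0))
            vals = self.mu[l, js] + sd[js] * rng.standard_normal(n)
            np.add.at(out, js, vals)
        return out / n


def _effect_loglik(V: float, r: np.ndarray, log_prior: np.ndarray) -> float:
    """Marginal log Bayes factor of one single effect with slab variance V."""
    lbf = -0.5 * np.log1p(V) + 0.5 * r * r * (V / (1.0 + V))
    return _logsum(lbf + log_prior) - _logsum(log_prior)


_V_GRID = np.exp(np.linspace(np.log(1e-6), np.log(1e8), 33))
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def estimate_prior_variance(residual_z: np.ndarray,
                            log_prior: np.ndarray | None = None,
                            v_max: float = 1e8) -> float:
    """Empirical-Bayes update of a single effect's slab variance.

    Maximizes the effect's marginal likelihood (the prior-weighted sum of
    per-coordinate Bayes factors) over V — a coarse log-spaced grid scan
    followed by golden-section refinement — and nulls the effect (returns
    0) whenever V = 0 fits at least as well.  Without the null check the
    variance of an empty effect decays only harmonically under plain EM
    updates and the effect never prunes.
    """
    r = np.asarray(residual_z, float)
    if log_prior is None:
        log_prior = np.full(r.size, -np.log(r.size))
    lp_norm = _logsum(log_prior)
    r2 = r * r
    # exact upper bound: each coordinate's Bayes factor maximized over its
    # own V; if even that cannot beat the null, the effect is empty
    with np.errstate(divide="ignore"):
        lbf_cap = np.where(r2 > 1.0, 0.5 * (r2 - 1.0 - np.log(r2)), 0.0)
    if _logsum(lbf_cap + log_prior) - lp_norm <= 0.0:
        return 0.0

    def f(V):
        lbf = -0.5 * np.log1p(V) + (V / (1.0 + V)) * (0.5 * r2)
        return _logsum(lbf + log_prior) - lp_norm

    grid = _V_GRID[_V_GRID <= v_max]
    shrink = (grid / (1.0 + grid))[:, None]
    vals_mat = -0.5 * np.log1p(grid)[:, None] + shrink * (0.5 * r * r)[None, :] \
        + log_prior[None, :]
    m = vals_mat.max(axis=1, keepdims=True)
    vals = (m.ravel() + np.log(np.exp(vals_mat - m).sum(axis=1))) - lp_norm
    i = int(np.argmax(vals))
    if vals[i] <= 0.0:       # the null fits at least as well everywhere
        return 0.0
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, grid.size - 1)])
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    for _ in range(16):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(np.exp(d))
    v = float(np.exp(0.5 * (a + b)))
    if f(v) <= 0.0 or v <= PRIOR_VARIANCE_FLOOR:
        return 0.0
    return v


def _single_effect_update(r: np.ndarray, V: float, log_prior: np.ndarray):
    """Single-effect regression of residual z-scores ``r`` (shat2 = 1)."""
    if V <= 0.0:
        p = r.size
        return np.full(p, 1.0 / p), np.zeros(p), np.zeros(p), 0.0
    # log Bayes factor of the slab against the null, per coordinate
    lbf = -0.5 * np.log1p(V) + 0.5 * r * r * (V / (1.0 + V))
    w = lbf + log_prior
    w_max = w.max()
    alpha = np.exp(w - w_max)
    alpha /= alpha.sum()
    post_var = V / (1.0 + V)
    mu = post_var * r
    mu2 = mu * mu + post_var
    # weighted log-BF of the whole effect (used in the objective)
    lbf_model = w_max + np.log(np.exp(w - w_max).sum()) - _logsum(log_prior)
    return alpha, mu, mu2, lbf_model


def _logsum(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _kl_terms(alpha, mu, mu2, V, log_prior) -> float:
    """Exact KL divergence of one single-effect posterior from its prior."""
    if V <= 0.0:
        return 0.0
    post_var = np.maximum(mu2 - mu * mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        cat = alpha * (np.log(np.maximum(alpha, 1e-300)) - log_prior)
    slab = 0.5 * (np.log(V / post_var) + (post_var + mu * mu) / V - 1.0)
    return float(np.sum(cat + alpha * slab))


def susie_rss(z: np.ndarray,
              corr: np.ndarray,
              L: int = 10,
              prior_variance: float = 50.0,
              prior_weights: np.ndarray | None = None,
              max_iter: int = 500,
              tol: float = 1e-6,
              estimate_prior: bool = True,
              coverage: float = 0.95,
              min_abs_corr: float = 0.1) -> SusieFit:
    """Fit the sum-of-single-effects model to z-scores and a correlation matrix.

    Parameters
    ----------
    z
        Marginal z-scores of the ``p`` candidate predictors.
    corr
        ``p x p`` correlation matrix of the predictors (unit diagonal;
        regularize upstream if rank deficient).
    L
        Number of single effects.
    prior_variance
        Initial slab variance of each effect on the z-coefficient scale.
        With ``estimate_prior`` the value is refined by EM and mainly sets
        the starting point.
    prior_weights
        Optional prior inclusion probabilities (default uniform).
    estimate_prior
        Update each effect's slab variance by empirical Bayes; effects whose
        variance collapses are pruned and report no credible set.
    coverage, min_abs_corr
        Credible-set level and purity filter passed to :func:`credible_sets`.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    corr = np.asarray(corr, dtype=float)
    p = z.size
    if corr.shape != (p, p):
        raise ValueError("corr shape does not match z")
    L = max(1, int(L))

    if prior_weights is None:
        log_prior = np.full(p, -np.log(p))
    else:
        w = np.asarray(prior_weights, dtype=float)
        w = w / w.sum()
        log_prior = np.log(np.maximum(w, 1e-300))

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    mu2 = np.zeros((L, p))
    V = np.full(L, float(prior_variance))

    Xb = np.zeros((L, p))   # per-effect fitted vectors corr @ (alpha_l mu_l)
    fitted = Xb.sum(axis=0)

    zz = float(z @ z)
    elbo_trace = []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        for l in range(L):
            fitted -= Xb[l]
            r = z - fitted
            if estimate_prior:
                V[l] = estimate_prior_variance(r, log_prior)
            alpha[l], mu[l], mu2[l], _ = _single_effect_update(r, V[l], log_prior)
            Xb[l] = corr @ (alpha[l] * mu[l])
            fitted += Xb[l]

        elbo = _objective(z, alpha, mu, mu2, V, log_prior, zz, Xb)
        elbo_trace.append(elbo)
        if it > 0 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break

    if not converged and max_iter > 1:
        warnings.warn("susie_rss did not converge within max_iter", RuntimeWarning)

    act = V > PRIOR_VARIANCE_FLOOR
    if act.any():
        pip = 1.0 - np.prod(1.0 - alpha[act], axis=0)
    else:
        pip = np.zeros(p)
    pip = np.clip(pip, 0.0, 1.0)

    fit = SusieFit(L=L, alpha=alpha, mu=mu, mu2=mu2, prior_variance=V,
                   pip=pip, credible_sets=[], converged=converged,
                   elbo_trace=np.array(elbo_trace), n_iter=n_iter)
    fit.credible_sets = credible_sets(fit, corr, coverage=coverage,
                                      min_abs_corr=min_abs_corr)
    return fit


def _objective(z, alpha, mu, mu2, V, log_prior, zz, Xb) -> float:
    """Mean-field variational objective (up to an additive constant).

    ``Xb`` carries the cached per-effect fitted vectors corr @ (alpha_l mu_l)
    so no matrix products are repeated here.
    """
    L, p = alpha.shape
    b_bar = (alpha * mu).sum(axis=0)
    quad = float(b_bar @ Xb.sum(axis=0))
    for l in range(L):
        b_l = alpha[l] * mu[l]
        quad -= float(b_l @ Xb[l])
        quad += float(alpha[l] @ mu2[l])  # diag(corr) == 1
    erss = zz - 2.0 * float(b_bar @ z) + quad
    kl = sum(_kl_terms(alpha[l], mu[l], mu2[l], V[l], log_prior)
             for l in range(L))
    return -0.5 * erss - kl


def credible_sets(fit: SusieFit, corr: np.ndarray, coverage: float = 0.95,
                  min_abs_corr: float = 0.1) -> list[CredibleSet]:
    """Smallest member set per active effect reaching ``coverage`` mass.

    Sets whose minimum absolute pairwise correlation falls below
    ``min_abs_corr`` are discarded (purity filter); duplicate member sets
    from different effects are reported once.
    """
    p = fit.alpha.shape[1]
    sets: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l in fit.active_effects:
        a = fit.alpha[l]
        order = np.lexsort((np.arange(p), -a))  # alpha desc, index asc
        cum = np.cumsum(a[order])
        k = int(np.searchsorted(cum, coverage) + 1)
        k = min(k, p)
        members = order[:k]
        if len(members) > 1:
            sub = np.abs(corr[np.ix_(members, members)])
            purity = float(sub.min())
        else:
            purity = 1.0
        if purity < min_abs_corr:
            continue
        key = frozenset(int(m) for m in members)
        if key in seen:
            continue
        seen.add(key)
        sets.append(CredibleSet(members=[int(m) for m in members],
                                cumulative_pip=float(cum[k - 1]),
                                purity=purity,
                                effect_index=int(l)))
    return sets
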