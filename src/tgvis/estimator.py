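"""The TGVIS estimator: joint fine-mapping of causal gene-tissue pairs and
direct causal variants with an infinitesimal (polygenic) variance component.

Model, on the GWAS z-score scale (a = GWAS z-vector, R = LD matrix, B =
stage-1 cis-effect matrix):

    a ~ N( R (B theta + gamma + upsilon), sigma_alpha^2 R ),
    upsilon ~ N(0, sigma_upsilon^2 I),

where ``theta`` holds causal gene-tissue pair effects, ``gamma`` sparse
direct variant effects, and ``upsilon`` dense infinitesimal effects.
Estimation alternates (profile likelihood):

1. (theta, gamma) by sum-of-single-effects selection on the
   infinitesimal-adjusted z-scores of the stacked design (pairs then
   variants);
2. upsilon by penalized quasi-likelihood, a ridge solve
   ``(R + I/sigma_upsilon^2)^{-1} (a - eta)``;
3. sigma_upsilon^2 by the REML fixed-point update.

The number of single effects L is chosen on a grid by a summary-data BIC,
and the infinitesimal component is gated by a variance-component score test
run once after an initial no-upsilon fit: if the null sigma_upsilon^2 = 0 is
accepted, upsilon is fixed at zero.  Final estimates are reported on the
standardized (per-SD of trait) scale; the fit is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cis_effects import CisEffectMatrix, fit_cis_effects, prescreen_pairs
from .susie import CredibleSet, SusieFit, susie_rss

logger = logging.getLogger("tgvis")

__all__ = [
    "TGVISConfig", "TGVISFit", "ScoreTestResult", "LocusEig",
    "stacked_inputs", "update_theta_gamma", "update_upsilon",
    "update_sigma_upsilon", "update_sigma_alpha", "profile_likelihood",
    "bic", "select_L", "score_test", "fit_tgvis",
]

DEFAULT_L_GRID = (2, 3, 4, 5, 6, 7, 8)


@dataclass
class TGVISConfig:
    l_grid: tuple = DEFAULT_L_GRID
    ld_eps: float = 1e-3              # ridge mixed into R before any solve
    prescreen_alpha: float = 0.05
    score_level: float = 0.05
    sigma_upsilon2_init: float = 1e-4
    upsilon_init_sv2: float = 0.5     # ridge strength of the upsilon-first start
    tol: float = 1e-5                 # relative max-norm change of (theta, gamma, upsilon)
    max_outer: int = 30
    susie_max_iter: int = 150
    coverage: float = 0.95
    min_abs_corr: float = 0.1
    cs_pratt_threshold: float = 0.15
    df_mode: str = "sets"             # "sets": one df per credible set; "members": per variable
    score_u_r_weighted: bool = False  # use (a - A v)' R^-1 (a - A v) in the score statistic


@dataclass
class ScoreTestResult:
    """Satterthwaite-type score test of H0: sigma_upsilon^2 = 0.

    Under H0 the score statistic ``u`` is distributed as kappa * chi^2_dof
    with kappa = h / (2 e) and dof = 2 e^2 / h.
    """

    u: float
    e: float
    h: float
    kappa: float
    dof: float
    p_value: float


class LocusEig:
    """Eigendecomposition of the regularized LD matrix with the solves the
    estimator needs (inverse, ridge inverse, square roots, traces)."""

    def __init__(self, R: np.ndarray, floor: float = 1e-8):
        vals, vecs = np.linalg.eigh(R)
        self.values = np.maximum(vals, floor)
        self.vectors = vecs
        self.tr_R2 = float(np.sum(self.values ** 2))

    def inv_mul(self, x: np.ndarray) -> np.ndarray:
        return self.vectors @ ((self.vectors.T @ x).T / self.values).T

    def ridge_solve(self, x: np.ndarray, lam: float) -> np.ndarray:
        return self.vectors @ ((self.vectors.T @ x) / (self.values + lam))

    def ridge_trace(self, lam: float) -> float:
        return float(np.sum(1.0 / (self.values + lam)))

    def quad_inv(self, x: np.ndarray) -> float:
        v = self.vectors.T @ x
        return float(np.sum(v * v / self.values))

    def sqrt_mul(self, x: np.ndarray) -> np.ndarray:
        return self.vectors @ ((self.vectors.T @ x).T * np.sqrt(self.values)).T

    def inv_sqrt_mul(self, x: np.ndarray) -> np.ndarray:
        return self.vectors @ ((self.vectors.T @ x).T / np.sqrt(self.values)).T


@dataclass
class TGVISFit:
    """Finalized fit.  Effect vectors are on the standardized trait scale;
    ``*_z`` attributes carry the same quantities on the z-score scale."""

    theta: np.ndarray                 # (P,) causal pair effects, zeros if unselected
    gamma: np.ndarray                 # (M,) direct causal variant effects
    upsilon: np.ndarray               # (M,) infinitesimal BLUPs
    sigma_alpha2: float
    sigma_upsilon2: float
    susie: SusieFit | None
    L_selected: int
    bic_trace: list
    score_test: ScoreTestResult | None
    n_iter: int
    converged: bool
    retained: np.ndarray              # stage-2 pair indices (stacked order)
    pair_weights: np.ndarray          # sqrt(b_j' R b_j) per retained pair
    credible_sets: list[CredibleSet]  # in stacked (retained pairs + variants) coords
    theta_z: np.ndarray = None
    gamma_z: np.ndarray = None
    upsilon_z: np.ndarray = None
    pratt: object = None              # PrattReport, attached by the pipeline
    infinitesimal_active: bool = False

    # -- helpers used by result writing and evaluation ------------------
    @property
    def n_pairs_retained(self) -> int:
        return self.retained.size

    def stacked_index(self, m: int) -> int:
        """Map a stacked-fit coordinate to the global (all pairs + variants)
        index space: pair j -> j, variant v -> n_pairs + v."""
        K = self.n_pairs_retained
        if m < K:
            return int(self.retained[m])
        return self.theta.size + (m - K)

    def pip_of(self, m: int) -> float:
        return float(self.susie.pip[m]) if self.susie is not None else 0.0

    def estimate_of(self, m: int) -> float:
        K = self.n_pairs_retained
        if m < K:
            return float(self.theta[self.retained[m]])
        return float(self.gamma[m - K])

    def pratt_of(self, m: int) -> float:
        if self.pratt is None:
            return float("nan")
        return float(self.pratt.per_variable[m])

    @property
    def cs_pratt(self) -> np.ndarray:
        if self.pratt is None:
            return np.full(len(self.credible_sets), np.nan)
        return self.pratt.per_set

    @property
    def pratt_components(self):
        if self.pratt is None:
            return (float("nan"),) * 3
        return self.pratt.components

    def variant_pips(self) -> np.ndarray:
        M = self.gamma.size
        if self.susie is None:
            return np.zeros(M)
        return self.susie.pip[self.n_pairs_retained:]

    def called_pairs(self) -> set[int]:
        """Gene-tissue pairs inside any reported 95% credible set."""
        K = self.n_pairs_retained
        out: set[int] = set()
        for cs in self.credible_sets:
            out.update(int(self.retained[m]) for m in cs.members if m < K)
        return out

    def called_variants(self) -> set[int]:
        """Variants (direct-effect coordinates) inside any credible set."""
        K = self.n_pairs_retained
        out: set[int] = set()
        for cs in self.credible_sets:
            out.update(m - K for m in cs.members if m >= K)
        return out

    def discovery_sets(self) -> list[list[int]]:
        """Credible sets mapped to global indices (pairs < P, variants >= P).

        Each set is one discovery: a single underlying causal signal whose
        members are statistically indistinguishable (often exactly tied,
        e.g. sibling tissues sharing one xQTL, or a one-xQTL pair and its
        variant twin).
        """
        return [[self.stacked_index(m) for m in cs.members]
                for cs in self.credible_sets]

    def causal_sets(self, threshold: float = 0.15) -> list[int]:
        """Indices of credible sets passing the CS-Pratt filter (strict >)."""
        vals = self.cs_pratt
        return [i for i in range(len(self.credible_sets))
                if np.isfinite(vals[i]) and vals[i] > threshold]


def stacked_inputs(ahat: np.ndarray, B: np.ndarray, R: np.ndarray):
    """Stacked z-scores and correlation matrix for the joint selection step.

    The design stacks the K predicted-expression scores G'b_j (normalized to
    unit variance) and the M variants.  Entries:

      z_pair_j = b_j' a / sqrt(b_j' R b_j),       z_variant = a,
      cor(pair j, pair k)   = b_j' R b_k / (w_j w_k),
      cor(pair j, variant m) = (R b_j)_m / w_j,    cor(variants) = R,

    with w_j = sqrt(b_j' R b_j).  Returns (z, corr, w).
    """
    ahat = np.asarray(ahat, float)
    B = np.asarray(B, float)
    if B.ndim == 1:
        B = B[:, None]
    K = B.shape[1]
    if K == 0:
        return ahat.copy(), R.copy(), np.zeros(0)
    RB = R @ B
    w2 = np.einsum("mk,mk->k", B, RB)
    if np.any(w2 <= 0):
        raise ValueError("zero-variance cis-effect column in stacked design")
    w = np.sqrt(w2)
    z_pairs = (B.T @ ahat) / w
    C_pp = (B.T @ RB) / np.outer(w, w)
    C_pv = (RB / w).T
    corr = np.block([[C_pp, C_pv], [C_pv.T, R]])
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    z = np.concatenate([z_pairs, ahat])
    return z, corr, w


def update_theta_gamma(z_adjusted: np.ndarray, corr: np.ndarray, L: int,
                       n_pairs: int, pair_weights: np.ndarray,
                       config: TGVISConfig) -> tuple[np.ndarray, np.ndarray, SusieFit]:
    """One (theta, gamma) selection step on infinitesimal-adjusted z-scores.

    Returns z-scale coefficients: theta_z per retained pair (posterior mean
    divided by the pair's normalization weight) and gamma_z per variant.
    """
    fit = susie_rss(z_adjusted, corr, L=L, max_iter=config.susie_max_iter,
                    coverage=config.coverage, min_abs_corr=config.min_abs_corr)
    bbar = fit.posterior_mean()
    # non-selected coordinates are exactly zero: only members of reported
    # credible sets carry effects; everything else is left to the
    # infinitesimal component (or the residual)
    mask = np.zeros(bbar.size, dtype=bool)
    for cs in fit.credible_sets:
        mask[cs.members] = True
    bbar = np.where(mask, bbar, 0.0)
    theta_z = bbar[:n_pairs] / pair_weights if n_pairs else np.zeros(0)
    gamma_z = bbar[n_pairs:]
    return theta_z, gamma_z, fit


def update_upsilon(ahat: np.ndarray, eta: np.ndarray, eig: LocusEig,
                   sigma_alpha2: float, sigma_upsilon2: float) -> np.ndarray:
    """PQL update of the infinitesimal BLUPs.

    upsilon = (R + lambda I)^{-1} (a - eta) with lambda the variance ratio;
    the ratio is taken as 1/sigma_upsilon^2 (sigma_alpha^2 profiled to 1)
    to avoid the non-identifiability of the two variance scales.
    """
    if sigma_upsilon2 <= 0:
        raise ValueError("sigma_upsilon2 must be positive for the PQL update")
    lam = sigma_alpha2 / sigma_upsilon2
    return eig.ridge_solve(ahat - eta, lam)


def update_sigma_upsilon(upsilon: np.ndarray, eig: LocusEig,
                         sigma_alpha2: float, sigma_upsilon2_prev: float,
                         M: int) -> float:
    """REML fixed-point update of the infinitesimal variance:
    ||upsilon||^2 / M + tr[(R + lambda I)^{-1}] / M, lambda from the
    previous iterate (again with sigma_alpha^2 profiled to 1)."""
    lam = sigma_alpha2 / sigma_upsilon2_prev
    return float(upsilon @ upsilon) / M + eig.ridge_trace(lam) / M


def update_sigma_alpha(ahat: np.ndarray, B: np.ndarray, theta_z: np.ndarray,
                       gamma_z: np.ndarray, upsilon_z: np.ndarray,
                       eig: LocusEig, R: np.ndarray) -> float:
    """Residual variance (a - R(B theta + gamma + upsilon))' R^{-1} (.) / M."""
    mean = gamma_z + upsilon_z
    if theta_z.size:
        mean = mean + B @ theta_z
    resid = ahat - R @ mean
    return eig.quad_inv(resid) / ahat.size


def bic(sigma_alpha2: float, M: int, df: float) -> float:
    """Summary-data BIC: log(sigma_alpha^2) + (log M / M) * df."""
    return float(np.log(max(sigma_alpha2, 1e-12)) + np.log(M) / M * df)


def _model_df(fit: SusieFit, mode: str = "sets") -> int:
    """Degrees of freedom of a stacked selection.

    "sets" counts one df per reported credible set (a set with several
    members represents a single underlying effect); "members" counts every
    selected variable.
    """
    if mode == "members":
        return sum(len(cs.members) for cs in fit.credible_sets)
    return len(fit.credible_sets)


def score_test(ahat: np.ndarray, A: np.ndarray, vartheta: np.ndarray,
               R: np.ndarray, eig: LocusEig,
               r_weighted_u: bool = False) -> ScoreTestResult:
    """Variance-component score test of H0: sigma_upsilon^2 = 0.

    ``A`` holds the selected fixed-effect columns [R B_sel, R_sel] and
    ``vartheta`` their z-scale estimates; with P the projection
    R^{-1} - R^{-1} A (A' R^{-1} A)^{-1} A' R^{-1} (P = R^{-1} for empty A):

        u = 0.5 ||a - A vartheta||^2,
        e = 0.5 tr(P R^2),   h = 0.5 tr(P R^2 P R^2),

    and under H0, u ~ kappa chi^2_dof with kappa = h/(2e), dof = 2e^2/h.
    Collinear columns of A are dropped with a warning.
    """
    M = ahat.size
    A = np.asarray(A, float)
    if A.ndim == 1:
        A = A[:, None]
    d = A.shape[1] if A.size else 0
    if d:
        # drop collinear columns via pivoted QR on the R^{-1/2}-whitened design
        W = eig.inv_sqrt_mul(A)
        _, rdiag, piv = _pivoted_qr(W)
        keep = piv[np.abs(rdiag) > 1e-8 * max(np.abs(rdiag).max(), 1e-300)]
        if keep.size < d:
            warnings.warn("score_test: dropped collinear selected columns",
                          RuntimeWarning)
            A = A[:, np.sort(keep)]
            vartheta = vartheta[np.sort(keep)]
            d = A.shape[1]
    if d:
        RiA = np.column_stack([eig.inv_mul(A[:, j]) for j in range(d)])
        G = A.T @ RiA
        K = np.linalg.inv(G)
        S1 = A.T @ A
        S2 = A.T @ (R @ A)
        KS1 = K @ S1
        e = 0.5 * (np.trace(R) - np.trace(KS1))
        h = 0.5 * (eig.tr_R2 - 2.0 * np.trace(K @ S2) + np.trace(KS1 @ KS1))
        resid = ahat - A @ vartheta
    else:
        e = 0.5 * np.trace(R)
        h = 0.5 * eig.tr_R2
        resid = ahat
    if r_weighted_u:
        u = 0.5 * eig.quad_inv(resid)
    else:
        u = 0.5 * float(resid @ resid)
    kappa = h / (2.0 * e)
    dof = 2.0 * e * e / h
    p = float(stats.chi2.sf(u / kappa, df=dof))
    return ScoreTestResult(u=float(u), e=float(e), h=float(h),
                           kappa=float(kappa), dof=float(dof), p_value=p)


def _pivoted_qr(W: np.ndarray):
    from scipy.linalg import qr
    _, r, piv = qr(W, mode="economic", pivoting=True)
    return None, np.diag(r) if r.ndim == 2 else np.atleast_1d(r[0]), piv


def _selected_design(fit: SusieFit, B: np.ndarray, R: np.ndarray,
                     theta_z: np.ndarray, gamma_z: np.ndarray):
    """Columns [R b_j, R e_m] and z-scale estimates for credible-set members."""
    K = B.shape[1]
    pair_sel, var_sel = [], []
    for cs in fit.credible_sets:
        for m in cs.members:
            (pair_sel if m < K else var_sel).append(m)
    pair_sel = sorted(set(pair_sel))
    var_sel = sorted(set(v - K for v in var_sel))
    cols, vals = [], []
    for j in pair_sel:
        cols.append(R @ B[:, j])
        vals.append(theta_z[j])
    for m in var_sel:
        cols.append(R[:, m])
        vals.append(gamma_z[m])
    if not cols:
        return np.zeros((R.shape[0], 0)), np.zeros(0)
    return np.column_stack(cols), np.array(vals)


def profile_likelihood(ahat: np.ndarray, B: np.ndarray, R: np.ndarray,
                       eig: LocusEig, L: int, config: TGVISConfig,
                       infinitesimal: bool | None = None,
                       stacked=None, fixed_sv2: float | None = None,
                       max_outer: int | None = None) -> dict:
    """Fit theta, gamma and upsilon at a fixed L.

    ``infinitesimal`` forces the component on/off; None lets the score test
    decide after the initial no-upsilon fit.  ``fixed_sv2`` freezes the
    infinitesimal variance (no REML update) — used when comparing fits
    across L, where re-estimating the variance at every L lets the BLUPs
    absorb arbitrarily much and makes fits incomparable.  ``stacked``
    optionally carries precomputed (z, corr, w) for the locus.  Returns a
    dict of z-scale results consumed by :func:`select_L`.
    """
    M = ahat.size
    K = B.shape[1]
    if stacked is None:
        stacked = stacked_inputs(ahat, B, R)
    z0, corr, w = stacked

    theta_z, gamma_z, fit = update_theta_gamma(z0, corr, L, K, w, config)
    st = None
    if infinitesimal is None:
        A, vals = _selected_design(fit, B, R, theta_z, gamma_z)
        st = score_test(ahat, A, vals, R, eig,
                        r_weighted_u=config.score_u_r_weighted)
        infinitesimal = st.p_value < config.score_level

    upsilon = np.zeros(M)
    sv2 = 0.0
    n_iter = 1
    converged = True
    if infinitesimal:
        converged = False
        # upsilon-first initialization: the first ridge pass absorbs a
        # moderate share of the *entire* signal (no selection protected),
        # so small effects sink into the polygenic background while
        # genuine signals still stand out for selection; the alternation
        # then frees selected coordinates from the BLUPs.  Selection-first
        # starts are sticky the other way: anything the first SuSiE pass
        # claims stays claimed, and the component never captures the small
        # effects it is meant to.
        sv2 = config.upsilon_init_sv2
        if fixed_sv2 is not None:
            sv2 = min(sv2, fixed_sv2) if fixed_sv2 > 0 else sv2
        theta_z = np.zeros(K)
        gamma_z = np.zeros(M)
        prev = None
        for s in range(max_outer or config.max_outer):
            n_iter = s + 1
            eta = R @ (B @ theta_z + gamma_z) if K else R @ gamma_z
            resid_proj = eig.vectors.T @ (ahat - eta)
            if fixed_sv2 is not None and s > 0:
                sv2 = fixed_sv2
            if fixed_sv2 is None and s > 0:
                # REML fixed point for the variance, iterated to
                # convergence in the eigenbasis.  The plain fixed-point
                # step is proportional to the variance itself (a near-zero
                # start crawls), hence the method-of-moments floor:
                # E||a - eta||^2 = M + sv2 tr(R^2).
                rss = float(resid_proj @ resid_proj)
                sv2 = max(sv2, (rss / M - 1.0) * M / eig.tr_R2, 1e-8)
                for _ in range(200):
                    lam = 1.0 / sv2
                    ups_proj = resid_proj / (eig.values + lam)
                    sv2_new = (float(ups_proj @ ups_proj) / M
                               + eig.ridge_trace(lam) / M)
                    if abs(sv2_new - sv2) < 1e-8 * max(sv2, 1e-12):
                        sv2 = sv2_new
                        break
                    sv2 = sv2_new
            ups_proj = resid_proj / (eig.values + 1.0 / sv2)
            upsilon = eig.vectors @ ups_proj
            Ru = R @ upsilon
            adj = np.concatenate([(B.T @ Ru) / w, Ru]) if K else Ru
            theta_z, gamma_z, fit = update_theta_gamma(z0 - adj, corr, L, K,
                                                       w, config)
            params = np.concatenate([theta_z, gamma_z, upsilon])
            scale = 1.0 + np.abs(params).max()
            if prev is not None and np.abs(params - prev).max() < config.tol * scale:
                converged = True
                break
            prev = params
        if not converged:
            logger.debug("profile likelihood: max_outer reached at L=%d", L)

    sa2 = update_sigma_alpha(ahat, B, theta_z, gamma_z, upsilon, eig, R)
    return {
        "L": L, "fit": fit, "theta_z": theta_z, "gamma_z": gamma_z,
        "upsilon_z": upsilon, "sigma_upsilon2": sv2, "sigma_alpha2": sa2,
        "score_test": st, "infinitesimal": infinitesimal,
        "n_iter": n_iter, "converged": converged,
        "df": _model_df(fit, config.df_mode),
    }


def select_L(ahat: np.ndarray, B: np.ndarray, R: np.ndarray, eig: LocusEig,
             config: TGVISConfig, retained: np.ndarray,
             n_pairs_total: int, n_trait: float) -> TGVISFit:
    """Choose L by BIC and fit the score-test-gated profile likelihood.

    A first pass evaluates BIC over the grid on no-infinitesimal fits and
    runs the score test once at the BIC minimizer.  If the test rejects,
    the infinitesimal variance is estimated by REML at that L and the grid
    is re-scanned with the component active at that *fixed* variance —
    fixed because re-estimating it at every L lets the BLUPs absorb
    arbitrarily much of whatever the sparse part misses, collapsing
    sigma_alpha^2 and making BIC degenerate.  With the ridge absorbing
    small effects, the re-scan typically settles on a sparser model than
    the no-upsilon pass.
    """
    if not config.l_grid:
        raise ValueError("empty L grid")
    M = ahat.size
    stacked = stacked_inputs(ahat, B, R) if B.shape[1] else (ahat, R, np.zeros(0))

    def scan(infinitesimal, fixed_sv2=None, max_outer=None):
        best = None
        trace = []
        for L in config.l_grid:
            res = profile_likelihood(ahat, B, R, eig, L, config,
                                     infinitesimal=infinitesimal,
                                     stacked=stacked, fixed_sv2=fixed_sv2,
                                     max_outer=max_outer)
            res["bic"] = bic(res["sigma_alpha2"], M, res["df"])
            trace.append({"L": L, "sigma_alpha2": res["sigma_alpha2"],
                          "df": res["df"], "bic": res["bic"],
                          "converged": res["converged"]})
            if best is None or res["bic"] < best["bic"]:
                best = res
        return best, trace

    best, trace = scan(infinitesimal=False)
    if best is None:
        raise RuntimeError("all profile-likelihood fits failed")

    A, vals = _selected_design(best["fit"], B, R, best["theta_z"],
                               best["gamma_z"])
    st0 = score_test(ahat, A, vals, R, eig,
                     r_weighted_u=config.score_u_r_weighted)
    if st0.p_value < config.score_level:
        ref = profile_likelihood(ahat, B, R, eig, best["L"], config,
                                 infinitesimal=True, stacked=stacked)
        sv2_star = max(ref["sigma_upsilon2"], 1e-8)
        best, trace = scan(infinitesimal=True, fixed_sv2=sv2_star,
                           max_outer=10)
        best = profile_likelihood(ahat, B, R, eig, best["L"], config,
                                  infinitesimal=True, stacked=stacked,
                                  fixed_sv2=sv2_star)
        best["bic"] = bic(best["sigma_alpha2"], M, best["df"])
        best["score_test"] = st0

    sqrt_n = np.sqrt(n_trait)
    theta = np.zeros(n_pairs_total)
    theta[retained] = best["theta_z"] / sqrt_n
    return TGVISFit(
        theta=theta,
        gamma=best["gamma_z"] / sqrt_n,
        upsilon=best["upsilon_z"] / sqrt_n,
        sigma_alpha2=best["sigma_alpha2"],
        sigma_upsilon2=best["sigma_upsilon2"],
        susie=best["fit"],
        L_selected=best["L"],
        bic_trace=trace,
        score_test=st0,
        n_iter=best["n_iter"],
        converged=best["converged"],
        retained=retained,
        pair_weights=stacked[2],
        credible_sets=best["fit"].credible_sets,
        theta_z=best["theta_z"],
        gamma_z=best["gamma_z"],
        upsilon_z=best["upsilon_z"],
        infinitesimal_active=bool(best["infinitesimal"]),
    )


def fit_tgvis(locus, config: TGVISConfig | None = None,
              B: CisEffectMatrix | None = None) -> TGVISFit:
    """Full TGVIS pipeline on a harmonized locus.

    Stage 1 fine-maps every pair's xQTLs, noise pairs are pre-screened out,
    stage 2 runs the profile likelihood with BIC selection of L and the
    score-test gate, and the Pratt report (per variable, per credible set,
    and the three component aggregates) is attached to the returned fit.
    """
    from .pratt import pratt_report

    config = config or TGVISConfig()
    R = locus.ld.regularized(config.ld_eps)
    eig = LocusEig(R)
    if B is None:
        B = fit_cis_effects(locus, R)
    keep = prescreen_pairs(locus.ahat, B, R, alpha=config.prescreen_alpha)
    Bsel = B.bmat[:, keep]
    fit = select_L(locus.ahat, Bsel, R, eig, config, retained=keep,
                   n_pairs_total=locus.n_pairs, n_trait=locus.n_trait)
    fit.pratt = pratt_report(fit, Bsel, locus.ahat, R, eig)
    return fit
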