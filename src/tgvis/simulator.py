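"""Synthetic GWAS + xQTL locus generator and benchmarking harness.

A locus is 20 genes x 5 tissues (100 gene-tissue pairs) over M = 400
variants with block-diagonal AR(1) LD.  Each pair has 1-4 causal xQTLs;
positions are shared within a gene across tissues (effect sizes correlated
across tissues) and partially shared between genes through a common pool,
creating the within- and between-gene correlation structure that makes the
selection problem hard.  Pairs 1 and 100 are causal for the trait with
effects +1 and -1; scenarios add two direct causal variants and/or dense
infinitesimal effects, each active component scaled to an equal share of
the local heritability.

Summary statistics are drawn directly at the summary level:

    a_z ~ N( sqrt(n_trait) R (B theta + gamma + upsilon) / s_y, R ),
    b_z(jt) ~ N( sqrt(n_eqtl) R beta_jt, R ),

where s_y (the trait SD in locus units) is set so the locus explains
``local_h2`` of trait variance.  The evaluation reports effects back on the
generating theta = +/-1 scale.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sumstats_io import LDMatrix, LocusData

logger = logging.getLogger("tgvis")

__all__ = ["SimConfig", "SimTruth", "build_ld", "simulate_locus",
           "evaluate", "run_benchmark", "aggregate"]

SCENARIOS = ("none", "direct", "infinitesimal", "both")


@dataclass
class SimConfig:
    n_genes: int = 20
    n_tissues: int = 5
    M: int = 400
    n_causal_xqtl: tuple = (1, 4)      # inclusive range per pair
    causal_pairs: tuple = (0, 99)
    causal_effects: tuple = (1.0, -1.0)
    n_eqtl: int = 200
    n_trait: float = 500_000.0
    scenario: str = "none"             # none | direct | infinitesimal | both
    n_direct_variants: int = 2         # used when scenario has direct effects
    local_h2: float = 0.0025           # locus share of trait variance
    expression_h2: float = 0.3         # cis-genetic share of expression variance
    block_size: int = 20
    ar_rho: float = 0.6
    cross_tissue_cor: float = 0.8      # effect-size correlation across tissues
    tissue_jitter: float = 0.25        # chance a tissue's xQTL shifts to an LD neighbor
    shared_pool_prob: float = 0.3      # chance an xQTL comes from the shared pool
    shared_pool_size: int = 30
    seed: int = 0

    @property
    def n_pairs(self) -> int:
        return self.n_genes * self.n_tissues

    def validate(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        lo, hi = self.n_causal_xqtl
        if not (1 <= lo <= hi <= self.M):
            raise ValueError("infeasible causal-xQTL range")
        if self.M % self.block_size:
            raise ValueError("M must be a multiple of block_size")
        if any(not 0 <= p < self.n_pairs for p in self.causal_pairs):
            raise ValueError("causal pair index out of range")

    @property
    def has_direct(self) -> bool:
        return self.scenario in ("direct", "both") and self.n_direct_variants > 0

    @property
    def has_infinitesimal(self) -> bool:
        return self.scenario in ("infinitesimal", "both")


@dataclass
class SimTruth:
    theta: np.ndarray                  # (P,) on the generating scale
    gamma: np.ndarray                  # (M,) trait-scale direct effects
    upsilon: np.ndarray                # (M,) trait-scale infinitesimal effects
    beta: np.ndarray                   # (M, P) expression-scale eQTL effects
    R: np.ndarray
    scale_y: float                     # trait SD in locus units
    component_variances: dict


def build_ld(M: int, block_size: int = 20, rho: float = 0.6) -> np.ndarray:
    """Block-diagonal AR(1) LD: within a block r_ij = rho^|i-j|, zero
    between blocks."""
    idx = np.arange(block_size)
    block = rho ** np.abs(idx[:, None] - idx[None, :])
    R = np.zeros((M, M))
    for start in range(0, M, block_size):
        R[start:start + block_size, start:start + block_size] = block
    return R


def _draw_eqtl_effects(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expression-scale eQTL matrix (M x P).

    Each gene draws 1-4 base causal positions (partially from a pool shared
    between genes); each tissue inherits the base positions but, with
    probability ``tissue_jitter`` per position, shifts to a nearby variant
    in the same LD block.  Effect sizes are correlated across tissues.
    This yields within-gene predictor correlations high enough to confuse
    selection without making sibling tissues exactly collinear (which a
    fully shared architecture would, whenever a gene has one causal xQTL).
    Every column is normalized to b'Rb = expression_h2.
    """
    M, T, bs = cfg.M, cfg.n_tissues, cfg.block_size
    R = build_ld(M, bs, cfg.ar_rho)
    pool = rng.choice(M, size=cfg.shared_pool_size, replace=False)
    rho_t = cfg.cross_tissue_cor
    cov_t = np.full((T, T), rho_t) + (1.0 - rho_t) * np.eye(T)
    chol_t = np.linalg.cholesky(cov_t)
    beta = np.zeros((M, cfg.n_pairs))
    lo, hi = cfg.n_causal_xqtl
    for g in range(cfg.n_genes):
        k = int(rng.integers(lo, hi + 1))
        pos: list[int] = []
        while len(pos) < k:
            if rng.random() < cfg.shared_pool_prob:
                cand = int(rng.choice(pool))
            else:
                cand = int(rng.integers(M))
            if cand not in pos:
                pos.append(cand)
        # per-position effects correlated across tissues
        eff = (chol_t @ rng.standard_normal((T, k))).T  # (k, T)
        for t in range(T):
            tpos = []
            for i in pos:
                j = i
                if rng.random() < cfg.tissue_jitter:
                    block = i // bs
                    j = i + int(rng.choice([-2, -1, 1, 2]))
                    j = min(max(j, block * bs), (block + 1) * bs - 1)
                tpos.append(j)
            col = np.zeros(M)
            for j, e in zip(tpos, eff[:, t]):
                col[j] += e
            denom = float(col @ R @ col)
            if denom <= 0:
                col[pos] = 1.0
                denom = float(col @ R @ col)
            beta[:, g * T + t] = col * np.sqrt(cfg.expression_h2 / denom)
    return beta


def simulate_locus(cfg: SimConfig) -> tuple[LocusData, SimTruth]:
    """Generate one synthetic locus; deterministic given ``cfg`` (incl. seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    M, P = cfg.M, cfg.n_pairs
    R = build_ld(M, cfg.block_size, cfg.ar_rho)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(M))

    beta = _draw_eqtl_effects(cfg, rng)
    theta = np.zeros(P)
    for idx, eff in zip(cfg.causal_pairs, cfg.causal_effects):
        theta[idx] = eff
    m_pairs = beta @ theta
    v_pairs = float(m_pairs @ R @ m_pairs)

    gamma = np.zeros(M)
    if cfg.has_direct:
        causal_xqtls = set(np.flatnonzero(beta.any(axis=1)))
        # spread direct variants over distinct blocks, away from causal xQTLs
        blocks = rng.permutation(M // cfg.block_size)
        chosen: list[int] = []
        for b in blocks:
            cand = [v for v in range(b * cfg.block_size, (b + 1) * cfg.block_size)
                    if v not in causal_xqtls]
            if cand:
                chosen.append(int(rng.choice(cand)))
            if len(chosen) == cfg.n_direct_variants:
                break
        g = np.sqrt(v_pairs / len(chosen)) if v_pairs > 0 else 1.0
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        gamma[chosen] = g * signs

    upsilon = np.zeros(M)
    sv2 = 0.0
    if cfg.has_infinitesimal:
        sv2 = v_pairs / M
        upsilon = rng.normal(0.0, np.sqrt(sv2), size=M)

    v_direct = float(gamma @ R @ gamma)
    v_inf = float(upsilon @ R @ upsilon)
    v_total = v_pairs + v_direct + v_inf
    if cfg.local_h2 > 0 and v_total > 0:
        scale_y = np.sqrt(v_total / cfg.local_h2)
        mu = (m_pairs + gamma + upsilon) / scale_y
    else:  # null locus: no genetic signal reaches the trait
        scale_y = 1.0
        mu = np.zeros(M)
    ahat = np.sqrt(cfg.n_trait) * (R @ mu) + chol @ rng.standard_normal(M)
    bhat = (np.sqrt(cfg.n_eqtl) * (R @ beta)
            + chol @ rng.standard_normal((M, P)))

    ids = [f"rs{i + 1}" for i in range(M)]
    variants = pd.DataFrame({
        "id": ids, "chrom": "1", "pos": np.arange(1, M + 1) * 1000,
        "a1": "A", "a2": "G",
        "beta": ahat / np.sqrt(cfg.n_trait), "se": 1.0 / np.sqrt(cfg.n_trait),
        "n": cfg.n_trait,
    })
    labels = [(f"gene{g + 1}", f"tissue{t + 1}")
              for g in range(cfg.n_genes) for t in range(cfg.n_tissues)]
    locus = LocusData(variants=variants, ahat=ahat, n_trait=cfg.n_trait,
                      bhat=bhat, n_xqtl=np.full(P, float(cfg.n_eqtl)),
                      pair_labels=labels, ld=LDMatrix(ids, R))
    truth = SimTruth(theta=theta, gamma=gamma, upsilon=upsilon, beta=beta,
                     R=R, scale_y=scale_y,
                     component_variances={"pairs": v_pairs,
                                          "direct": v_direct,
                                          "infinitesimal": v_inf})
    return locus, truth


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def evaluate(fits: dict, truth: SimTruth, scale_back: bool = True) -> list[dict]:
    """Per-replicate metrics for each method's fit.

    A true negative requires no non-causal pair called causal; a true
    positive requires both causal pairs called.  For credible-set methods
    one set is one discovery — its members are statistically tied
    representations of a single signal — so a pair-containing set counts as
    a correct pair discovery iff it contains a causal pair, a pure-variant
    set counts as one direct-variant call, and a causal pair counts as
    found when any set contains it.  All methods are scored on their
    reported 95% credible sets.  Effect estimates are rescaled by the
    generating trait SD so the MSE is on the theta = +/-1 scale.  When a method reports an identically-zero infinitesimal vector
    its recovery correlation is recorded as 0.
    """
    causal = set(np.flatnonzero(truth.theta))
    P = truth.theta.size
    s = truth.scale_y if scale_back else 1.0
    rows = []
    for method, fit in fits.items():
        theta_hat = fit.theta * s
        sets = fit.discovery_sets()
        pair_sets = [set(g for g in mem if g < P) for mem in sets]
        tn = int(all((ps & causal) for ps in pair_sets if ps))
        tp = int(all(any(c in ps for ps in pair_sets) for c in causal))
        n_direct = sum(1 for mem in sets if all(g >= P for g in mem))
        row = {
            "method": method,
            "mse_theta": float(np.mean((theta_hat - truth.theta) ** 2)),
            "tn": tn,
            "tp": tp,
            "n_direct_called": n_direct,
        }
        if np.any(truth.gamma != 0):
            row["cor_gamma"] = _safe_cor(fit.gamma * s, truth.gamma)
        if np.any(truth.upsilon != 0):
            ups = getattr(fit, "upsilon", None)
            if ups is None:
                ups = np.zeros_like(truth.upsilon)
            row["cor_upsilon"] = _safe_cor(ups * s, truth.upsilon)
        rows.append(row)
    return rows


def run_benchmark(scenarios=SCENARIOS, n_eqtl=(200,), methods=("tgvis",),
                  n_reps: int = 10, seed: int = 0,
                  sim_overrides: dict | None = None,
                  config=None, tgfm_outer: int = 100,
                  baseline_L: int = 5) -> pd.DataFrame:
    """Cross scenarios x xQTL sample sizes x methods over seeded replicates.

    Child seeds are spawned deterministically from the master seed, so the
    same (seed, grid) always produces identical tables.  Method failures on
    a replicate are recorded with ``error`` set and the cell left partial.
    """
    from .cis_effects import fit_cis_effects
    from .estimator import LocusEig, TGVISConfig, fit_tgvis
    from . import baselines

    config = config or TGVISConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for scen in scenarios:
        for ne in n_eqtl:
            children = ss.spawn(n_reps)
            for rep, child in enumerate(children):
                rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
                cfg = SimConfig(scenario=scen, n_eqtl=int(ne), seed=rep_seed)
                if sim_overrides:
                    cfg = replace(cfg, **sim_overrides)
                locus, truth = simulate_locus(cfg)
                R = locus.ld.regularized(config.ld_eps)
                eig = LocusEig(R)
                B = fit_cis_effects(locus, R)
                fits = {}
                for method in methods:
                    try:
                        if method == "tgvis":
                            fits[method] = fit_tgvis(locus, config, B=B)
                        elif method == "ctwas":
                            fits[method] = baselines.ctwas_like(
                                locus, B, L=baseline_L, config=config,
                                eig=eig, R=R)
                        elif method == "tgfm":
                            fits[method] = baselines.tgfm_like(
                                locus, B, L=baseline_L, seed=rep_seed,
                                outer=tgfm_outer, config=config,
                                eig=eig, R=R)
                        else:
                            raise ValueError(f"unknown method {method!r}")
                    except Exception as exc:  # record, keep the cell partial
                        logger.warning("%s failed on %s/%d rep %d: %s",
                                       method, scen, ne, rep, exc)
                        rows.append({"scenario": scen, "n_eqtl": ne,
                                     "rep": rep, "method": method,
                                     "error": str(exc)})
                for r in evaluate(fits, truth):
                    r.update({"scenario": scen, "n_eqtl": ne, "rep": rep})
                    rows.append(r)
    return pd.DataFrame(rows)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per scenario x n_eqtl x method (errors excluded)."""
    ok = results
    if "error" in results.columns:
        ok = results[results["error"].isna()]
    metrics = [c for c in ("mse_theta", "tn", "tp", "n_direct_called",
                           "cor_gamma", "cor_upsilon") if c in ok.columns]
    return (ok.groupby(["scenario", "n_eqtl", "method"])[metrics]
              .mean().reset_index())
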