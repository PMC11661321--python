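"""Reading, harmonization and writing of locus-level summary statistics.

Inputs are GWAS and xQTL (eQTL/sQTL) marginal summary statistics over one
locus, plus an LD correlation matrix of the locus variants.  Everything is
harmonized into a single :class:`LocusData` container: one shared variant
order (the LD-matrix order), alleles aligned so that every effect refers to
the same effect allele, and effects carried internally as z-scores together
with their sample sizes (the standardized-trait scale is recovered as
``z / sqrt(n)`` whenever needed).

Matching is by variant ID primarily, with chrom:pos:alleles as a fallback.
Strand-ambiguous (A/T, C/G) variants are dropped by default; multi-allelic
IDs (same ID, different allele pairs) are dropped and logged.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tgvis")

DEFAULT_COLUMNS = {
    "id": "SNP", "chrom": "CHR", "pos": "BP",
    "a1": "A1", "a2": "A2", "beta": "BETA", "se": "SE", "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class LDMatrix:
    """LD correlation matrix ``r`` over an ordered list of variant IDs."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant_ids")
        if np.abs(self.r - self.r.T).max() > 1e-8:
            raise ValueError("LD matrix is not symmetric")
        self.r = 0.5 * (self.r + self.r.T)

    def regularized(self, eps: float = 1e-3) -> np.ndarray:
        """Return ``(1 - eps) R + eps I``.

        Reference-panel LD is frequently rank deficient (panel smaller than
        the variant count); the ridge makes every solve and inverse in the
        estimator well posed.
        """
        m = self.r.shape[0]
        return (1.0 - eps) * self.r + eps * np.eye(m)

    def subset(self, idx: np.ndarray) -> "LDMatrix":
        ids = [self.variant_ids[i] for i in idx]
        return LDMatrix(ids, self.r[np.ix_(idx, idx)])


@dataclass
class LocusData:
    """Harmonized locus container shared by every estimator in the package.

    ``ahat`` holds GWAS z-scores and ``bhat`` the M x (pairs) matrix of xQTL
    z-scores, both in LD-matrix variant order and aligned to the same effect
    alleles.  Standardized-scale effects are ``z / sqrt(n)``.
    """

    variants: pd.DataFrame          # id, chrom, pos, a1, a2 (+ beta, se, n)
    ahat: np.ndarray                # (M,) GWAS z-scores
    n_trait: float
    bhat: np.ndarray                # (M, P) xQTL z-scores
    n_xqtl: np.ndarray              # (P,) per-pair sample sizes
    pair_labels: list[tuple[str, str]]
    ld: LDMatrix

    @property
    def n_variants(self) -> int:
        return self.ahat.size

    @property
    def n_pairs(self) -> int:
        return self.bhat.shape[1]


def read_gwas(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistics table.

    ``column_map`` maps canonical names (id, chrom, pos, a1, a2, beta, se, n)
    to the file's column headers; unmapped names fall back to the GWAS
    conventions SNP/CHR/BP/A1/A2/BETA/SE/N.  Rows with missing fields,
    non-positive SE or N, or identical alleles are dropped with a logged
    count.  gzip input is handled transparently.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise KeyError(f"required columns not found in {path.name}: {missing}")
    out = pd.DataFrame({k: df[v] for k, v in cols.items()})
    for c in ("pos", "beta", "se", "n"):
        out[c] = pd.to_numeric(out[c], errors="coerce")
    n0 = len(out)
    out = out.dropna()
    out = out[(out["se"] > 0) & (out["n"] > 0)]
    out["a1"] = out["a1"].str.upper()
    out["a2"] = out["a2"].str.upper()
    out = out[out["a1"] != out["a2"]]
    # multi-allelic: same ID appearing with several allele pairs -> drop all
    dup = out["id"].duplicated(keep=False)
    if dup.any():
        out = out[~dup]
    dropped = n0 - len(out)
    if dropped:
        logger.warning("read_gwas(%s): dropped %d invalid/duplicate rows",
                       path.name, dropped)
    if len(out) == 0:
        raise ValueError(f"no usable rows in {path}")
    return out.reset_index(drop=True)


read_xqtl = read_gwas  # identical table layout; one file per gene-tissue pair


def read_ld(path) -> LDMatrix:
    """Read an LD matrix: dense text with a header row of variant IDs, or
    PLINK ``.ld`` long format (SNP_A, SNP_B, R columns)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
    if {"SNP_A", "SNP_B", "R"}.issubset(header):
        long = pd.read_csv(path, sep=r"\s+")
        ids = sorted(set(long["SNP_A"]) | set(long["SNP_B"]))
        index = {v: i for i, v in enumerate(ids)}
        m = len(ids)
        r = np.eye(m)
        for a, b, val in zip(long["SNP_A"], long["SNP_B"], long["R"]):
            r[index[a], index[b]] = val
            r[index[b], index[a]] = val
        return LDMatrix(ids, r)
    mat = pd.read_csv(path, sep=r"\s+")
    return LDMatrix(list(mat.columns), mat.to_numpy(dtype=float))


def _allele_sign(row, ref_a1: str, ref_a2: str) -> float:
    """+1 if alleles match the reference orientation, -1 if swapped, 0 if
    irreconcilable."""
    a1, a2 = row
    if (a1, a2) == (ref_a1, ref_a2):
        return 1.0
    if (a1, a2) == (ref_a2, ref_a1):
        return -1.0
    # strand flip
    c1, c2 = _COMPLEMENT.get(a1, "?"), _COMPLEMENT.get(a2, "?")
    if (c1, c2) == (ref_a1, ref_a2):
        return 1.0
    if (c1, c2) == (ref_a2, ref_a1):
        return -1.0
    return 0.0


def harmonize(gwas: pd.DataFrame,
              xqtl: dict[tuple[str, str], pd.DataFrame],
              ld: LDMatrix,
              drop_ambiguous: bool = True) -> LocusData:
    """Intersect GWAS, xQTL and LD variants and align alleles and signs.

    The GWAS table defines the reference allele orientation.  Variants
    missing from any source, strand-ambiguous variants (by default) and
    variants whose alleles cannot be reconciled by swap and/or strand flip
    are dropped with a logged count.  Output order is LD-matrix order.
    """
    g = gwas.set_index("id")
    shared = [v for v in ld.variant_ids if v in g.index]
    if drop_ambiguous:
        keep = [v for v in shared
                if not _is_ambiguous(g.at[v, "a1"], g.at[v, "a2"])]
        if len(keep) < len(shared):
            logger.info("harmonize: dropped %d strand-ambiguous variants",
                        len(shared) - len(keep))
        shared = keep
    pair_tables = {}
    for label, tab in xqtl.items():
        pair_tables[label] = tab.set_index("id")
    for label, t in pair_tables.items():
        shared = [v for v in shared if v in t.index]
    if not shared:
        raise ValueError("no variants shared by GWAS, xQTL and LD inputs")

    idx = np.array([ld.variant_ids.index(v) for v in shared])
    ld_sub = ld.subset(idx)

    gsub = g.loc[shared]
    ahat = (gsub["beta"] / gsub["se"]).to_numpy(dtype=float)
    n_trait = float(gsub["n"].median())

    labels = list(pair_tables)
    M, P = len(shared), len(labels)
    bhat = np.zeros((M, P))
    n_xqtl = np.zeros(P)
    bad: set[str] = set()
    for jp, label in enumerate(labels):
        t = pair_tables[label].loc[shared]
        signs = np.array([
            _allele_sign((t.at[v, "a1"], t.at[v, "a2"]),
                         gsub.at[v, "a1"], gsub.at[v, "a2"])
            for v in shared
        ])
        bad.update(np.array(shared)[signs == 0.0])
        bhat[:, jp] = signs * (t["beta"] / t["se"]).to_numpy(dtype=float)
        n_xqtl[jp] = float(t["n"].median())
    if bad:
        logger.warning("harmonize: dropping %d variants with irreconcilable "
                       "alleles", len(bad))
        keep = np.array([v not in bad for v in shared])
        shared = [v for v, k in zip(shared, keep) if k]
        if not shared:
            raise ValueError("no variants left after allele reconciliation")
        ahat = ahat[keep]
        bhat = bhat[keep]
        ld_sub = ld_sub.subset(np.flatnonzero(keep))
        gsub = gsub.loc[shared]

    variants = gsub.reset_index()[["id", "chrom", "pos", "a1", "a2",
                                   "beta", "se", "n"]]
    return LocusData(variants=variants, ahat=ahat, n_trait=n_trait,
                     bhat=bhat, n_xqtl=n_xqtl, pair_labels=labels,
                     ld=ld_sub)


def write_results(fit, locus: LocusData, out_dir, run_meta: dict | None = None):
    """Write the result tables of a finalized fit.

    Produces, in ``out_dir``: ``credible_sets.tsv`` (one row per member:
    set ID, variable, type, PIP, estimate, per-variable Pratt, cumulative
    set PIP, CS-Pratt, purity), ``direct_variants.tsv``,
    ``infinitesimal.tsv`` (per-variant BLUPs), and ``run_info.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    P = locus.n_pairs

    def _var_name(stacked_idx: int) -> str:
        if stacked_idx < P:
            g, t = locus.pair_labels[stacked_idx]
            return f"{g}:{t}"
        return str(locus.variants["id"].iloc[stacked_idx - P])

    rows = []
    for s, cs in enumerate(fit.credible_sets):
        for m in cs.members:
            rows.append({
                "cs_id": f"cs{s + 1}",
                "variable": _var_name(fit.stacked_index(m)),
                "type": "pair" if fit.stacked_index(m) < P else "variant",
                "pip": fit.pip_of(m),
                "estimate": fit.estimate_of(m),
                "pratt": fit.pratt_of(m),
                "cs_pip": cs.cumulative_pip,
                "cs_pratt": fit.cs_pratt[s],
                "purity": cs.purity,
            })
    cols = ["cs_id", "variable", "type", "pip", "estimate", "pratt",
            "cs_pip", "cs_pratt", "purity"]
    pd.DataFrame(rows, columns=cols).to_csv(out / "credible_sets.tsv",
                                            sep="\t", index=False)

    dv = pd.DataFrame({
        "variant": locus.variants["id"],
        "gamma": fit.gamma,
        "pip": fit.variant_pips(),
    })
    dv[dv["gamma"] != 0.0].to_csv(out / "direct_variants.tsv", sep="\t",
                                  index=False)

    pd.DataFrame({
        "variant": locus.variants["id"],
        "upsilon": fit.upsilon,
    }).to_csv(out / "infinitesimal.tsv", sep="\t", index=False)

    meta = {
        "L_selected": fit.L_selected,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "sigma_alpha2": fit.sigma_alpha2,
        "sigma_upsilon2": fit.sigma_upsilon2,
        "score_test_p": fit.score_test.p_value if fit.score_test else float("nan"),
        "pratt_pairs": fit.pratt_components[0],
        "pratt_variants": fit.pratt_components[1],
        "pratt_infinitesimal": fit.pratt_components[2],
    }
    if run_meta:
        meta.update(run_meta)
    pd.DataFrame([meta]).to_csv(out / "run_info.tsv", sep="\t", index=False)
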