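"""Summary-statistics I/O: parsing, harmonization, result round-trips."""

import gzip

import numpy as np
import pandas as pd
import pytest

from tgvis import (LDMatrix, fit_tgvis, harmonize, read_gwas, read_ld,
                   write_results)
from tgvis.estimator import TGVISConfig
from conftest import make_sumstats_frame


def _write(path, df, colmap=None):
    cols = {"id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
            "beta": "BETA", "se": "SE", "n": "N"}
    out = df.rename(columns=cols)
    if colmap:
        out = out.rename(columns={cols[k]: v for k, v in colmap.items()})
    out.to_csv(path, sep="\t", index=False)
    return path


def test_read_gwas_parses_and_validates(tmp_path):
    df = make_sumstats_frame(["rs1", "rs2", "rs3"], "AAG", "GGT",
                             [0.1, -0.2, 0.05])
    p = _write(tmp_path / "g.tsv", df)
    got = read_gwas(p)
    assert len(got) == 3
    np.testing.assert_allclose(got["beta"], [0.1, -0.2, 0.05])


def test_read_gwas_drops_invalid_rows(tmp_path, caplog):
    df = make_sumstats_frame(["rs1", "rs2", "rs3"], "AAG", "GGT",
                             [0.1, -0.2, 0.05], se=[1.0, 0.0, 1.0])
    p = _write(tmp_path / "g.tsv", df)
    got = read_gwas(p)
    assert list(got["id"]) == ["rs1", "rs3"]


def test_read_gwas_column_map_equivalence(tmp_path):
    df = make_sumstats_frame(["rs1", "rs2"], "AC", "GT", [0.3, 0.4])
    p1 = _write(tmp_path / "a.tsv", df)
    p2 = _write(tmp_path / "b.tsv", df, colmap={"id": "variant",
                                                "beta": "effect"})
    t1 = read_gwas(p1)
    t2 = read_gwas(p2, {"id": "variant", "beta": "effect"})
    pd.testing.assert_frame_equal(t1, t2)


def test_read_gwas_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_gwas(tmp_path / "missing.tsv")
    df = make_sumstats_frame(["rs1"], "A", "G", [0.1], se=[0.0])
    p = _write(tmp_path / "allbad.tsv", df)
    with pytest.raises(ValueError):
        read_gwas(p)
    with pytest.raises(KeyError):
        read_gwas(_write(tmp_path / "c.tsv", make_sumstats_frame(
            ["rs1"], "A", "G", [0.1])), {"id": "NOPE"})


def _tiny_inputs():
    ids = ["rs1", "rs2", "rs3", "rs4", "rs5"]
    gwas = make_sumstats_frame(ids, "ACGAC", "GTACT", [0.1, 0.2, -0.1, 0.3, 0.0])
    xq = make_sumstats_frame(ids, "ACGAC", "GTACT", [1.0, -1.0, 0.5, 0.2, 0.1])
    r = np.eye(5)
    ld = LDMatrix(ids, r)
    return gwas, xq, ld


def test_harmonize_identity_and_order():
    gwas, xq, ld = _tiny_inputs()
    locus = harmonize(gwas, {("g1", "t1"): xq}, ld, drop_ambiguous=False)
    assert list(locus.variants["id"]) == ld.variant_ids
    np.testing.assert_allclose(locus.ahat, gwas["beta"] / gwas["se"])
    np.testing.assert_allclose(locus.bhat[:, 0], xq["beta"] / xq["se"])


def test_harmonize_flips_swapped_alleles():
    gwas, xq, ld = _tiny_inputs()
    xq2 = xq.copy()
    xq2.loc[1, ["a1", "a2"]] = ["T", "C"]   # swap of rs2's C/T alleles
    locus = harmonize(gwas, {("g1", "t1"): xq2}, ld, drop_ambiguous=False)
    assert locus.bhat[1, 0] == pytest.approx(-(xq["beta"][1] / xq["se"][1]))


def test_harmonize_drops_strand_ambiguous():
    gwas, xq, ld = _tiny_inputs()
    gwas.loc[3, ["a1", "a2"]] = ["A", "T"]  # ambiguous site
    xq.loc[3, ["a1", "a2"]] = ["A", "T"]
    locus = harmonize(gwas, {("g1", "t1"): xq}, ld)
    assert locus.n_variants == 4
    assert "rs4" not in list(locus.variants["id"])


def test_harmonize_idempotent_and_flip_invariant():
    gwas, xq, ld = _tiny_inputs()
    locus1 = harmonize(gwas, {("g1", "t1"): xq}, ld, drop_ambiguous=False)
    # run harmonize again on its own output representation
    g2 = locus1.variants.copy()
    locus2 = harmonize(g2, {("g1", "t1"): xq}, ld, drop_ambiguous=False)
    np.testing.assert_allclose(locus1.ahat, locus2.ahat)
    np.testing.assert_allclose(locus1.bhat, locus2.bhat)
    # flipping every allele pair and sign in the xQTL table changes nothing
    xq_f = xq.copy()
    xq_f[["a1", "a2"]] = xq_f[["a2", "a1"]].to_numpy()
    xq_f["beta"] = -xq_f["beta"]
    locus3 = harmonize(gwas, {("g1", "t1"): xq_f}, ld, drop_ambiguous=False)
    np.testing.assert_allclose(locus1.bhat, locus3.bhat)


def test_harmonize_empty_intersection_raises():
    gwas, xq, ld = _tiny_inputs()
    other = LDMatrix(["rsX"], np.eye(1))
    with pytest.raises(ValueError):
        harmonize(gwas, {("g1", "t1"): xq}, other)


def test_read_ld_dense_and_plink_long(tmp_path):
    ids = ["rs1", "rs2", "rs3"]
    r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
    dense = tmp_path / "ld.tsv"
    pd.DataFrame(r, columns=ids).to_csv(dense, sep="\t", index=False)
    got = read_ld(dense)
    np.testing.assert_allclose(got.r, r)
    rows = [(a, b, r[i, j]) for i, a in enumerate(ids)
            for j, b in enumerate(ids) if i < j]
    long = pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R"])
    plink = tmp_path / "plink.ld"
    long.to_csv(plink, sep="\t", index=False)
    got2 = read_ld(plink)
    np.testing.assert_allclose(got2.r, r)
    assert got2.variant_ids == ids


def test_ld_regularization_is_positive_definite():
    ids = ["a", "b"]
    ld = LDMatrix(ids, np.array([[1.0, 1.0], [1.0, 1.0]]))
    w = np.linalg.eigvalsh(ld.regularized(1e-3))
    assert w.min() > 0


def test_write_results_roundtrip(tmp_path, small_locus):
    locus, _ = small_locus
    fit = fit_tgvis(locus, TGVISConfig(l_grid=(2, 3)))
    out = tmp_path / "res"
    write_results(fit, locus, out, run_meta={"seed": 1})
    cs = pd.read_csv(out / "credible_sets.tsv", sep="\t")
    info = pd.read_csv(out / "run_info.tsv", sep="\t")
    blup = pd.read_csv(out / "infinitesimal.tsv", sep="\t")
    assert len(blup) == locus.n_variants
    assert info.loc[0, "L_selected"] == fit.L_selected
    # members grouped per set with the set-level statistics repeated
    if len(cs):
        for sid, grp in cs.groupby("cs_id"):
            assert grp["cs_pratt"].nunique() == 1
        total_members = sum(len(s.members) for s in fit.credible_sets)
        assert len(cs) == total_members
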