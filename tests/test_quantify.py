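import numpy as np
import pandas as pd
import pytest

from extruscan.contacts import ContactMatrix
from extruscan.quantify import (
    call_degs,
    compute_fpkm,
    fold_change,
    gene_contact_probability,
    peak_enrichment,
    rpm_profile,
)
from extruscan.simulate import simulate_expression
from extruscan.annotation import build_locus_annotation
from extruscan.core import ProcessivityParams


# ---------------------------------------------------------------------------
# FPKM


def test_fpkm_unit_case():
    counts = pd.DataFrame({"s1": [10]}, index=["g1"])
    fpkm = compute_fpkm(counts, lengths=pd.Series({"g1": 1000}),
                        library_sizes=pd.Series({"s1": 1e6}))
    assert fpkm.loc["g1", "s1"] == pytest.approx(10.0)


def test_fpkm_scale_invariance():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 500, size=(20, 4)).astype(float))
    lengths = pd.Series(rng.integers(200, 5000, size=20).astype(float))
    a = compute_fpkm(counts, lengths=lengths)
    b = compute_fpkm(2 * counts, lengths=lengths)  # library sizes double too
    pd.testing.assert_frame_equal(a, b)


def test_fpkm_matches_bruteforce_formula():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(0, 1000, size=(30, 5)).astype(float))
    lengths = pd.Series(rng.integers(100, 8000, size=30).astype(float))
    libs = pd.Series(rng.integers(10**6, 10**7, size=5).astype(float))
    got = compute_fpkm(counts, lengths=lengths, library_sizes=libs).to_numpy()
    expected = np.empty_like(got)
    for i in range(30):
        for j in range(5):
            expected[i, j] = counts.iat[i, j] * 1e9 / (lengths.iloc[i] * libs.iloc[j])
    assert np.allclose(got, expected, rtol=1e-12, atol=0)


def test_fpkm_rejects_degenerate_inputs():
    counts = pd.DataFrame({"s1": [1]}, index=["g1"])
    with pytest.raises(ValueError):
        compute_fpkm(counts, lengths=pd.Series({"g1": 0}))
    with pytest.raises(ValueError):
        compute_fpkm(counts, lengths=pd.Series({"g1": 100}),
                     library_sizes=pd.Series({"s1": 0}))
    with pytest.raises(ValueError):
        peak_enrichment(counts, peak_lengths=pd.Series({"g1": 0}))


# ---------------------------------------------------------------------------
# Fold change and DEGs


def test_fold_change_identity():
    wt = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
    fc = fold_change(wt, wt.copy(), pseudo=0.0)
    assert fc.loc[0, "log2fc"] == 0.0
    assert fc.loc[0, "p"] == pytest.approx(1.0)


def test_fold_change_simple_ratio():
    wt = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"])
    mut = pd.DataFrame([[4.0, 4.0, 4.0]], index=["g"])
    fc = fold_change(wt, mut, pseudo=0.0)
    assert fc.loc[0, "log2fc"] == pytest.approx(2.0)


def test_fold_change_single_replicate_flagged():
    wt = pd.DataFrame([[1.0]], index=["g"])
    mut = pd.DataFrame([[2.0]], index=["g"])
    fc = fold_change(wt, mut)
    assert np.isnan(fc.loc[0, "p"]) and np.isnan(fc.loc[0, "padj"])
    assert np.isfinite(fc.loc[0, "log2fc"])


def test_null_simulation_type_one_error():
    """p < 0.05 on ~nominal fraction of null NB genes (Welch with n=3 runs
    slightly conservative)."""
    rng = np.random.default_rng(42)
    phi, mu, n = 0.05, 200.0, 1000

    def nb(size):
        return rng.poisson(rng.gamma(1 / phi, mu * phi, size=size)).astype(float)

    fc = fold_change(pd.DataFrame(nb((n, 3))), pd.DataFrame(nb((n, 3))))
    frac = float((fc["p"] < 0.05).mean())
    assert 0.02 <= frac <= 0.07


def test_bh_adjustment_monotone_in_rank():
    rng = np.random.default_rng(3)
    wt = pd.DataFrame(rng.gamma(5, 10, size=(200, 3)))
    mut = pd.DataFrame(rng.gamma(5, 11, size=(200, 3)))
    fc = fold_change(wt, mut).sort_values("p")
    padj = fc["padj"].to_numpy()
    assert np.all(np.diff(padj) >= -1e-12)
    assert np.all(fc["padj"].to_numpy() >= fc["p"].to_numpy() - 1e-12)


def test_deg_thresholds_are_strict():
    table = pd.DataFrame(
        {
            "gene_id": ["at_lfc", "at_padj", "down", "up"],
            "log2fc": [0.5, 1.0, -0.8, 0.8],
            "p": [0.001] * 4,
            "padj": [0.01, 0.05, 0.01, 0.01],
        }
    )
    degs = call_degs(table)
    assert "at_lfc" not in degs.all  # log2FC == 0.5 excluded
    assert "at_padj" not in degs.all  # padj == 0.05 excluded
    assert degs.down == ("down",) and degs.up == ("up",)


def test_empty_table_yields_empty_degset():
    empty = pd.DataFrame(columns=["gene_id", "log2fc", "p", "padj"])
    degs = call_degs(empty)
    assert degs.all == ()


def test_planted_down_genes_recovered():
    """28 strongly downregulated genes planted among ~2000 null background
    genes are nearly all recovered by the default DEG calling."""
    ann = build_locus_annotation()
    p = ProcessivityParams(lambda_mut=400_000)  # null cluster effect
    cm, truth = simulate_expression(
        ann,
        p,
        seed=2024,
        replicates=5,
        background_de_fraction=28 / 2000,
        background_de_log2fc=3.0,
        background_de_down_fraction=1.0,
        background_fpkm_log_sd=0.5,
    )
    planted = set(truth["planted_background_degs"])
    assert len(planted) == 28
    fpkm = compute_fpkm(cm)
    fc = fold_change(fpkm[cm.condition_columns("WT")], fpkm[cm.condition_columns("mut")])
    degs = call_degs(fc)
    assert len(planted & set(degs.down)) >= 27


# ---------------------------------------------------------------------------
# RPM


def test_rpm_forced_values_and_conservation():
    rpm = rpm_profile(np.array([1.0, 1.0, 2.0]))
    assert np.allclose(rpm, [250_000, 250_000, 500_000])
    rng = np.random.default_rng(4)
    track = rng.integers(0, 100, size=500).astype(float)
    track[0] = 1  # ensure nonzero
    out = rpm_profile(track)
    assert out.sum() == pytest.approx(1e6)
    assert np.allclose(out, track * 1e6 / track.sum(), rtol=1e-12)


def test_rpm_rejects_empty_track():
    with pytest.raises(ValueError):
        rpm_profile(np.zeros(10))


# ---------------------------------------------------------------------------
# Virtual 4C per-gene contact


def _toy_matrix(annotation, seed=0):
    lo, hi = annotation.locus_span
    start = lo - 100_000
    n = (hi + 100_000 - start) // 10_000
    rng = np.random.default_rng(seed)
    m = rng.poisson(5.0, size=(n, n)).astype(float)
    m = (m + m.T) / 2
    return ContactMatrix(matrix=m, bin_size=10_000, chrom="chrS", start=start)


def test_gene_contact_matches_bruteforce_overlap_sum(small_annotation):
    mat = _toy_matrix(small_annotation)
    vals = gene_contact_probability(mat, "HS5-1", small_annotation)
    lo_e, hi_e = small_annotation.enhancer_interval("HS5-1")
    row = mat.matrix[mat.bin_index((lo_e + hi_e) // 2)]
    row = row * 1e6 / row.sum()
    starts = mat.bin_starts()
    for _, g in small_annotation.cluster_genes.iterrows():
        expected = sum(
            row[i]
            for i in range(mat.n_bins)
            if starts[i] < g["exon_end"] and starts[i] + mat.bin_size > g["exon_start"]
        )
        assert vals[g["gene_id"]] == pytest.approx(expected, rel=1e-12)


def test_gene_contact_zero_without_overlapping_signal(small_annotation):
    mat = _toy_matrix(small_annotation)
    lo_e, hi_e = small_annotation.enhancer_interval("HS5-1")
    e = mat.bin_index((lo_e + hi_e) // 2)
    g0 = small_annotation.cluster_genes.iloc[[0]]
    # zero out the bins covering the first gene's exon
    mat.matrix[e, :] = 0
    mat.matrix[:, e] = 0
    mat.matrix[e, e + 1] = mat.matrix[e + 1, e] = 100.0  # keep the row nonzero
    vals = gene_contact_probability(mat, "HS5-1", small_annotation, genes=g0)
    assert vals.iloc[0] == 0.0


def test_identical_intervals_get_identical_values(small_annotation):
    mat = _toy_matrix(small_annotation, seed=9)
    g = small_annotation.cluster_genes.iloc[[3, 3]].copy()
    g["gene_id"] = ["copyA", "copyB"]
    vals = gene_contact_probability(mat, "HS5-1bL", small_annotation, genes=g)
    assert vals["copyA"] == vals["copyB"]


def test_anchor_outside_matrix_errors(small_annotation):
    mat = _toy_matrix(small_annotation)
    shifted = ContactMatrix(
        matrix=mat.matrix, bin_size=mat.bin_size, chrom=mat.chrom, start=0
    )
    with pytest.raises(ValueError):
        gene_contact_probability(shifted, "HS5-1", small_annotation)
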