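import numpy as np
import pandas as pd
import pytest

from extruscan.contacts import ContactMatrix
from extruscan.simulate import simulate_contact_matrix, simulate_tad_benchmark_matrix
from extruscan.topology import (
    call_tads,
    differential_contact_map,
    directionality_index,
    fit_hmm,
    kr_balance,
    normalize_depth,
)


def _random_symmetric(n, seed=0, low=0.5, high=5.0):
    rng = np.random.default_rng(seed)
    m = rng.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2
    return ContactMatrix(matrix=m, bin_size=10_000)


# ---------------------------------------------------------------------------
# Depth normalization


def test_depth_scaling_factor():
    m = ContactMatrix(matrix=np.full((10, 10), 2e4), bin_size=1)  # total 2e6
    out = normalize_depth(m, target=1e8)
    assert out.cis_total() == pytest.approx(1e8)
    assert np.allclose(out.matrix / m.matrix, 50.0)


def test_depth_normalization_identity_and_ratios():
    m = _random_symmetric(30, seed=2)
    at_target = normalize_depth(m, target=m.cis_total())
    assert np.allclose(at_target.matrix, m.matrix)
    out = normalize_depth(m, target=12345.0)
    ratio_before = m.matrix[3, 7] / m.matrix[11, 20]
    ratio_after = out.matrix[3, 7] / out.matrix[11, 20]
    assert ratio_after == pytest.approx(ratio_before, rel=1e-12)


def test_depth_normalization_rejects_empty():
    with pytest.raises(ValueError):
        normalize_depth(ContactMatrix(matrix=np.zeros((3, 3)), bin_size=1))


# ---------------------------------------------------------------------------
# KR balancing


def test_kr_two_by_two_closed_form():
    m = ContactMatrix(matrix=np.array([[2.0, 1.0], [1.0, 2.0]]), bin_size=1)
    out = kr_balance(m)
    assert np.allclose(out.weights, 1 / np.sqrt(3), rtol=1e-7)
    assert np.allclose(out.matrix, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], rtol=1e-7)
    assert np.allclose(out.matrix.sum(axis=1), 1.0, rtol=1e-7)


def test_kr_balances_random_matrices_to_uniform_rows():
    for seed in range(3):
        m = _random_symmetric(200, seed=seed)
        out = kr_balance(m)
        rows = out.matrix.sum(axis=1)
        assert rows.std() / rows.mean() < 1e-6


def test_kr_idempotent_on_balanced_matrix():
    m = _random_symmetric(50, seed=7)
    once = kr_balance(m)
    twice = kr_balance(once)
    assert np.allclose(twice.weights, 1.0, atol=1e-6)


def test_kr_masks_empty_bins():
    m = _random_symmetric(20, seed=1)
    mat = m.matrix.copy()
    mat[5, :] = 0.0
    mat[:, 5] = 0.0
    out = kr_balance(ContactMatrix(matrix=mat, bin_size=1))
    assert np.isnan(out.weights[5])
    rows = np.delete(out.matrix.sum(axis=1), 5)
    assert np.allclose(rows, 1.0, rtol=1e-6)


# ---------------------------------------------------------------------------
# Directionality index


def test_di_zero_when_windows_balance():
    m = np.zeros((3, 3))
    m[1, 0] = m[0, 1] = 10.0
    m[1, 2] = m[2, 1] = 10.0
    di = directionality_index(ContactMatrix(matrix=m, bin_size=1), window=1)
    assert di.di[1] == 0.0


def test_di_formula_worked_example():
    # A=10 upstream, B=20 downstream: E=15, DI = (25/15 + 25/15) = 10/3
    m = np.zeros((3, 3))
    m[1, 0] = m[0, 1] = 10.0
    m[1, 2] = m[2, 1] = 20.0
    di = directionality_index(ContactMatrix(matrix=m, bin_size=1), window=1)
    assert di.di[1] == pytest.approx(10 / 3)
    assert di.truncated[0] and di.truncated[2]


def test_di_antisymmetric_under_mirror():
    m = _random_symmetric(60, seed=4)
    di = directionality_index(m, window=8).di
    mirrored = ContactMatrix(matrix=m.matrix[::-1, ::-1].copy(), bin_size=10_000)
    di_m = directionality_index(mirrored, window=8).di
    assert np.allclose(di_m, -di[::-1], equal_nan=True)


def test_di_requires_positive_window():
    with pytest.raises(ValueError):
        directionality_index(_random_symmetric(5), window=0)


# ---------------------------------------------------------------------------
# HMM decoding


def test_posteriors_normalized_and_switch_detected():
    rng = np.random.default_rng(0)
    di = np.concatenate([
        np.full(10, 5.0), np.full(10, -5.0)
    ]) + rng.normal(0, 0.05, 20)
    post = fit_hmm(di, seed=0)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
    states = post.to_numpy().argmax(axis=1)
    assert (states[:10] == states[0]).all()
    assert (states[10:] == states[10]).all()
    assert states[0] != states[10]
    # labels ordered by emission mean: positive DI block is downstream-biased
    assert post.columns[states[0]] == "downstream"
    assert post.columns[states[10]] == "upstream"


def test_constant_track_collapses_to_single_state():
    post = fit_hmm(np.zeros(30), seed=0)
    states = post.to_numpy().argmax(axis=1)
    assert len(set(states)) == 1


def test_hmm_reproducible_under_seed():
    rng = np.random.default_rng(5)
    di = rng.normal(0, 1, 200)
    a = fit_hmm(di, seed=3)
    b = fit_hmm(di, seed=3)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# TAD calling filters and assembly


def _posteriors(spec):
    """Build a posterior frame from (state, n_bins, prob) runs."""
    cols = ["upstream", "none", "downstream"]
    rows = []
    for state, n, p in spec:
        for _ in range(n):
            row = {c: (1 - p) / 2 for c in cols}
            row[state] = p
            rows.append(row)
    return pd.DataFrame(rows)[cols]


def test_short_region_excluded():
    post = _posteriors([("none", 5, 1.0), ("downstream", 2, 1.0), ("none", 5, 1.0)])
    tads = call_tads(post)
    reg = tads.regions
    short = reg[(reg["state"] == "downstream")]
    assert not short["retained"].iloc[0]
    assert short["reason"].iloc[0] == "too_few_bins"


def test_low_posterior_region_excluded():
    post = _posteriors([("none", 5, 1.0), ("downstream", 5, 0.95), ("none", 5, 1.0)])
    tads = call_tads(post)
    reg = tads.regions[tads.regions["state"] == "downstream"]
    assert not reg["retained"].iloc[0]
    assert reg["reason"].iloc[0] == "low_posterior"
    assert tads.domains == []


def test_domains_span_downstream_to_upstream_runs():
    post = _posteriors(
        [
            ("downstream", 5, 1.0),
            ("none", 10, 1.0),
            ("upstream", 5, 1.0),
            ("downstream", 4, 1.0),
            ("upstream", 4, 1.0),
        ]
    )
    tads = call_tads(post)
    assert tads.domains == [(0, 20), (20, 28)]
    assert tads.boundaries == [0, 20, 28]


def test_planted_boundaries_recovered_in_benchmark_matrix():
    mat, planted = simulate_tad_benchmark_matrix(seed=12)
    bal = kr_balance(normalize_depth(mat, 1e8))
    di = directionality_index(bal, window=100)
    tads = call_tads(fit_hmm(di, seed=0))
    called = np.array(tads.boundaries)
    hits = sum(1 for b in planted if np.min(np.abs(called - b)) <= 1)
    assert hits >= 7  # at least 7 of the 8 planted boundaries within +/- 1 bin
    for _, reg in tads.regions[tads.regions["retained"]].iterrows():
        assert reg["n_bins"] >= 3 and reg["median_posterior"] >= 0.99


# ---------------------------------------------------------------------------
# Differential map


def test_differential_map_zero_and_antisymmetric():
    a = _random_symmetric(25, seed=8)
    b = _random_symmetric(25, seed=9)
    assert np.all(differential_contact_map(a, a) == 0)
    assert np.allclose(
        differential_contact_map(a, b), -differential_contact_map(b, a)
    )
    diff = differential_contact_map(a, b)
    assert np.allclose(diff, diff.T)


def test_differential_map_shape_mismatch():
    with pytest.raises(ValueError):
        differential_contact_map(_random_symmetric(10), _random_symmetric(12))


def test_mutant_differential_depletes_beta_more_than_gamma(annotation, params):
    """enhancer x beta-promoter pixels lose more contact than
    enhancer x gamma-promoter pixels in the mutant - WT difference map."""
    wt, info = simulate_contact_matrix(annotation, params, condition="WT", seed=21)
    mut, _ = simulate_contact_matrix(annotation, params, condition="mut", seed=22)
    diff = differential_contact_map(
        normalize_depth(wt, 1e8), normalize_depth(mut, 1e8)
    )
    genes = annotation.cluster_genes

    def pixel_mean(cluster, element):
        e = info["enhancer_viewpoint_bins"][element]
        sub = genes[genes["cluster"] == cluster]
        bins = sorted({wt.bin_index(int(a)) for a in sub["anchor"]})
        return diff[e, bins].mean()

    assert pixel_mean("beta", "HS21") < pixel_mean("gamma", "HS5-1bL")
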