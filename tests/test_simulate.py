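import numpy as np
import pandas as pd
import pytest

from extruscan.core import ProcessivityParams, expected_expression_log2fc
from extruscan.simulate import (
    gene_distances,
    simulate_chip_and_4c,
    simulate_contact_matrix,
    simulate_expression,
    simulate_tad_benchmark_matrix,
)


def test_expression_is_reproducible_under_seed(small_annotation, params):
    a, _ = simulate_expression(small_annotation, params, seed=7)
    b, _ = simulate_expression(small_annotation, params, seed=7)
    assert a.counts.equals(b.counts)
    c, _ = simulate_expression(small_annotation, params, seed=8)
    assert not a.counts.equals(c.counts)


def test_decoupled_expression_has_zero_expected_fold_change(small_annotation):
    p = ProcessivityParams(expression_coupling=0.0)
    _, truth = simulate_expression(small_annotation, p, seed=1)
    assert all(v == 0.0 for v in truth["expected_log2fc"].values())


def test_empirical_log2fc_matches_generator_closed_form(small_annotation):
    """Per-gene mean empirical log2FC over 50 seeds agrees with
    -eta*d*Delta(1/lambda)/ln2 within Monte-Carlo error."""
    p = ProcessivityParams(background_contact_scale=0.0)
    d = gene_distances(small_annotation)
    theory = expected_expression_log2fc(d.to_numpy(), p)
    per_seed = []
    for seed in range(50):
        cm, _ = simulate_expression(small_annotation, p, seed=seed)
        wt = cm.counts[cm.condition_columns("WT")].mean(axis=1)
        mut = cm.counts[cm.condition_columns("mut")].mean(axis=1)
        per_seed.append(np.log2(mut.loc[d.index] / wt.loc[d.index]).to_numpy())
    per_seed = np.array(per_seed)
    mean = per_seed.mean(axis=0)
    se = per_seed.std(axis=0, ddof=1) / np.sqrt(per_seed.shape[0])
    z = (mean - theory) / se
    # 3-SE agreement for the vast majority of the 58 genes (a ~0.3% tail
    # plus the small log-of-mean bias allows an occasional 3-4 SE gene)
    assert np.mean(np.abs(z) < 3) >= 0.93
    assert np.all(np.abs(z) < 5)


def test_contact_matrix_symmetric_with_planted_boundaries(annotation, params):
    mat, info = simulate_contact_matrix(annotation, params, seed=3)
    assert np.array_equal(mat.matrix, mat.matrix.T)
    assert info["boundary_bins"] == sorted(info["boundary_bins"])
    # bookkeeping: emitted boundary bins match the bp positions
    assert [
        mat.start + b * mat.bin_size for b in info["boundary_bins"]
    ] == info["boundaries_bp"]
    assert mat.cis_total() > 0


def test_mutant_loses_distal_enhancer_contacts(annotation, params):
    """Expected enhancer-row contact mass beyond 500 kb is lower in the
    mutant; checked as a mean over 20 seed pairs."""
    deficits = []
    for seed in range(20):
        sums = {}
        for cond in ("WT", "mut"):
            mat, info = simulate_contact_matrix(
                annotation, params, condition=cond, seed=100 + seed
            )
            e = info["enhancer_viewpoint_bins"]["HS5-1"]
            row = mat.matrix[e] / mat.cis_total()
            sep = np.abs(np.arange(mat.n_bins) - e) * mat.bin_size
            sums[cond] = row[sep > 500_000].sum()
        deficits.append(sums["mut"] - sums["WT"])
    assert np.mean(deficits) < 0


def test_benchmark_matrix_respects_domain_constraints():
    mat, boundaries = simulate_tad_benchmark_matrix(seed=5)
    assert mat.n_bins == 500
    assert len(boundaries) == 8
    gaps = np.diff([0] + boundaries + [500])
    assert gaps.min() >= 25
    assert np.array_equal(mat.matrix, mat.matrix.T)


def test_hs7_analog_peak_is_processivity_blind(small_annotation, params):
    chip, _ = simulate_chip_and_4c(small_annotation, params, seed=2)
    ratios = chip.truth["expected_ratio"]
    assert ratios["HS7"] == 1.0
    # all CTCF-site elements are attenuated
    for name in ("HS5-1", "HS5-1bL", "HS18-20", "HS21", "HS22", "HS7L"):
        assert ratios[name] < 1.0


def test_beta_peaks_drop_more_than_gamma_peaks(small_annotation, params):
    """Cluster-mean mutant/WT peak ratio: beta < gamma, over 20 seeds."""
    genes = small_annotation.cluster_genes.set_index("gene_id")
    means = {"beta": [], "gamma": []}
    for seed in range(20):
        chip, _ = simulate_chip_and_4c(small_annotation, params, seed=seed)
        wt = chip.counts.counts[chip.counts.condition_columns("WT")].mean(axis=1)
        mut = chip.counts.counts[chip.counts.condition_columns("mut")].mean(axis=1)
        for cl in means:
            ids = genes[genes["cluster"] == cl].index
            means[cl].append(float((mut.loc[ids] / wt.loc[ids]).mean()))
    assert np.mean(means["beta"]) < np.mean(means["gamma"])


def test_4c_tracks_reproducible_and_viewpoint_validated(small_annotation, params):
    _, t1 = simulate_chip_and_4c(small_annotation, params, seed=11)
    _, t2 = simulate_chip_and_4c(small_annotation, params, seed=11)
    for key in t1:
        pd.testing.assert_frame_equal(t1[key], t2[key])
    with pytest.raises(KeyError):
        simulate_chip_and_4c(
            small_annotation, params, seed=1, fourc_viewpoints=("HS-nonexistent",)
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"depth": 0},
        {"nb_dispersion": -0.1},
        {"replicates": 0},
    ],
)
def test_expression_input_validation(small_annotation, params, kwargs):
    with pytest.raises(ValueError):
        simulate_expression(small_annotation, params, seed=1, **kwargs)


def test_contact_matrix_input_validation(small_annotation, params):
    with pytest.raises(ValueError):
        simulate_contact_matrix(small_annotation, params, bin_size=0, seed=1)
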