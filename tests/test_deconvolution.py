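import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurodeconv as nd
from neurodeconv.errors import CoverageError
from neurodeconv.selection import DeconvolutionModel


def _model(mu, fractions=None):
    mu = np.asarray(mu, dtype=float)
    fractions = fractions or [f"f{k}" for k in range(mu.shape[1])]
    return DeconvolutionModel(
        site_ids=[f"cg{i}" for i in range(mu.shape[0])],
        mu=mu,
        fraction_labels=fractions,
        method="anova",
    )


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(42)
    return _model(rng.random((60, 3)))


def test_pure_profile_yields_unit_weight_vector(toy_model):
    for k in range(3):
        w, n = nd.project_cell_types(toy_model.mu[:, k], toy_model)
        expected = np.zeros(3)
        expected[k] = 1.0
        np.testing.assert_allclose(w, expected, atol=1e-8)
        assert n == toy_model.n_sites


def test_exact_linear_combination_recovered(toy_model):
    bulk = 0.3 * toy_model.mu[:, 0] + 0.7 * toy_model.mu[:, 1]
    w, _ = nd.project_cell_types(bulk, toy_model)
    np.testing.assert_allclose(w, [0.3, 0.7, 0.0], atol=1e-6)


def test_noisy_projection_matches_grid_search_oracle(grid_search_oracle):
    """NNLS solution agrees with a brute-force 0.001-resolution grid search."""
    rng = np.random.default_rng(7)
    mu = rng.random((40, 3))
    for trial in range(5):
        w_true = rng.dirichlet([2, 2, 2])
        bulk = np.clip(mu @ w_true + rng.normal(0, 0.02, 40), 0, 1)
        w_fit, _ = nd.project_cell_types(bulk, mu)
        w_oracle = grid_search_oracle(bulk, mu, resolution=0.001)
        np.testing.assert_allclose(w_fit, w_oracle, atol=2e-3)
        # objective of the fit is no worse than the oracle's
        obj = lambda w: np.sum((bulk - mu @ w) ** 2)
        assert obj(w_fit) <= obj(w_oracle) + 1e-10


def test_cetygo_zero_for_exact_reconstruction(toy_model):
    bulk = toy_model.mu @ np.array([0.25, 0.25, 0.5])
    w, _ = nd.project_cell_types(bulk, toy_model)
    assert nd.cetygo_score(bulk, toy_model, w) <= 1e-12


def test_cetygo_hand_value():
    """Residuals (0.1, -0.1) over 2 sites give sqrt((0.01 + 0.01)/2) = 0.1."""
    mu = np.array([[0.5], [0.5]])
    bulk = np.array([0.6, 0.4])
    score = nd.cetygo_score(bulk, mu, np.array([1.0]))
    assert score == pytest.approx(0.1, abs=1e-12)


def test_cetygo_interpretive_flag():
    assert nd.interpret_cetygo(0.12) == "incomplete/incorrect reference panel"
    assert nd.interpret_cetygo(0.05) is None


def test_cetygo_invariant_to_site_permutation(toy_model):
    rng = np.random.default_rng(1)
    bulk = np.clip(toy_model.mu @ np.array([0.2, 0.3, 0.5]) + rng.normal(0, 0.05, 60), 0, 1)
    w, _ = nd.project_cell_types(bulk, toy_model)
    s0 = nd.cetygo_score(bulk, toy_model.mu, w)
    perm = rng.permutation(60)
    s1 = nd.cetygo_score(bulk[perm], toy_model.mu[perm], w)
    assert s0 == pytest.approx(s1, abs=1e-14)


def test_fitted_weights_minimise_cetygo(toy_model):
    rng = np.random.default_rng(2)
    bulk = np.clip(toy_model.mu @ np.array([0.4, 0.1, 0.5]) + rng.normal(0, 0.03, 60), 0, 1)
    w_fit, _ = nd.project_cell_types(bulk, toy_model)
    best = nd.cetygo_score(bulk, toy_model, w_fit)
    for _ in range(25):
        other = rng.random(3) * 1.2
        assert best <= nd.cetygo_score(bulk, toy_model, other) + 1e-12


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 2.0), min_size=3, max_size=3))
def test_fitted_weights_beat_arbitrary_nonnegative_weights(w_other):
    """Property: the fitted CETYGO lower-bounds the CETYGO of any
    non-negative weight vector on the same sites."""
    rng = np.random.default_rng(99)
    mu = rng.random((50, 3))
    bulk = np.clip(mu @ np.array([0.35, 0.25, 0.4]) + rng.normal(0, 0.02, 50), 0, 1)
    w_fit, _ = nd.project_cell_types(bulk, mu)
    assert nd.cetygo_score(bulk, mu, w_fit) <= nd.cetygo_score(bulk, mu, np.array(w_other)) + 1e-12


def test_cetygo_increases_with_noise(toy_model):
    """Monte-Carlo trend: larger injected noise, larger expected CETYGO."""
    rng = np.random.default_rng(3)
    clean = toy_model.mu @ np.array([0.3, 0.3, 0.4])
    means = []
    for sd in (0.01, 0.05, 0.1):
        scores = []
        for _ in range(30):
            bulk = np.clip(clean + rng.normal(0, sd, 60), 0, 1)
            w, _ = nd.project_cell_types(bulk, toy_model)
            scores.append(nd.cetygo_score(bulk, toy_model, w))
        means.append(np.mean(scores))
    assert means[0] < means[1] < means[2]


def test_missing_sites_dropped_and_coverage_enforced(toy_model):
    bulk = toy_model.mu @ np.array([0.5, 0.5, 0.0])
    partial = bulk.copy()
    partial[:20] = np.nan  # 40/60 sites left
    with pytest.warns(UserWarning, match="covers"):
        w, n = nd.project_cell_types(partial, toy_model)
    assert n == 40
    np.testing.assert_allclose(w, [0.5, 0.5, 0.0], atol=1e-6)
    too_sparse = bulk.copy()
    too_sparse[: 40] = np.nan  # 20/60 < 50%
    with pytest.raises(CoverageError):
        nd.project_cell_types(too_sparse, toy_model)


def test_rank_deficient_reference_warns(toy_model):
    mu = np.column_stack([toy_model.mu[:, 0], toy_model.mu[:, 0]])
    bulk = mu[:, 0] * 0.8
    with pytest.warns(UserWarning, match="rank deficient"):
        w, _ = nd.project_cell_types(bulk, mu)
    assert w.sum() == pytest.approx(0.8, abs=1e-6)


def test_sum_constrained_variants(toy_model):
    rng = np.random.default_rng(4)
    bulk = np.clip(toy_model.mu @ np.array([0.5, 0.4, 0.3]) + rng.normal(0, 0.01, 60), 0, 1)
    w_le, _ = nd.project_cell_types(bulk, toy_model, constraint="sumleq")
    assert w_le.sum() <= 1 + 1e-8
    w_eq, _ = nd.project_cell_types(bulk, toy_model, constraint="sumeq")
    assert w_eq.sum() == pytest.approx(1.0, abs=1e-8)


def test_batch_deconvolve_contract(toy_model):
    sites = toy_model.site_ids
    bulk_df = pd.DataFrame(
        {
            "b1": toy_model.mu[:, 0],
            "b2": toy_model.mu @ np.array([0.2, 0.8, 0.0]),
            "b3": np.full(60, np.nan),
        },
        index=sites,
    )
    # b3 has no usable values -> flagged row, not an abort
    bulk_df["b3"] = np.nan
    bulk = nd.MethylationMatrix(bulk_df)
    res = nd.deconvolve(bulk, toy_model)
    assert list(res["sample_id"]) == ["b1", "b2", "b3"]
    np.testing.assert_allclose(
        res.loc[0, toy_model.fraction_labels].to_numpy(dtype=float), [1, 0, 0], atol=1e-6
    )
    np.testing.assert_allclose(
        res.loc[1, toy_model.fraction_labels].to_numpy(dtype=float), [0.2, 0.8, 0], atol=1e-6
    )
    assert res.loc[2, "flag"].startswith("error:")
    assert res["weight_sum"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_out_of_panel_cell_type_raises_cetygo(reference):
    """Bulk containing a cell type absent from the panel (astrocytes) scores
    higher CETYGO than in-panel mixtures (incomplete-reference analogue)."""
    ref, sheet = reference
    panel = nd.PanelSpec(
        "no_astro",
        ("NeuNPos/SOX6Pos", "NeuNNeg/SOX10Pos", "NeuNNeg/SOX10Neg/IRF8Pos"),
    )
    model = nd.anova_select(ref, sheet, panel, n_per_type=50)
    grid = nd.composition_grid(3).rows
    rng = np.random.default_rng(9)

    def profiles_for(fractions):
        return np.column_stack(
            [
                ref.data.loc[
                    model.site_ids,
                    rng.choice(sheet.loc[sheet["fraction_label"] == f, "sample_id"]),
                ]
                for f in fractions
            ]
        )

    in_panel = profiles_for(panel.fraction_labels)
    # swap the microglial component for astrocytes, which no panel column covers
    out_panel = profiles_for(
        ("NeuNPos/SOX6Pos", "NeuNNeg/SOX10Pos", "NeuNNeg/SOX10Neg/IRF8Neg")
    )

    def scores(profiles):
        out = []
        for w_true in grid:
            bulk = profiles @ w_true
            w, _ = nd.project_cell_types(bulk, model)
            out.append(nd.cetygo_score(bulk, model, w))
        return np.array(out)

    assert np.median(scores(out_panel)) > np.median(scores(in_panel))
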