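import numpy as np
import pandas as pd
import pytest

import neurodeconv as nd
from neurodeconv.errors import ApplicabilityError, ParameterError, SelectionError
from neurodeconv.projection import project_many


def _tiny_ref(values, fractions):
    sites = [f"cg{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    matrix = nd.MethylationMatrix(pd.DataFrame(values, index=sites, columns=samples))
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "fraction_label": fractions,
            "individual_id": [f"i{j}" for j in range(values.shape[1])],
            "batch": None,
        }
    )
    return matrix, sheet


def test_reference_means_by_hand():
    values = np.array([[0.2, 0.4, 0.6, 0.8], [0.1, 0.1, 0.5, 0.5]])
    ref, sheet = _tiny_ref(values, ["a", "a", "a", "b"])
    mu = nd.compute_reference_means(ref, sheet, ["cg0", "cg1"])
    assert mu.loc["cg0", "a"] == pytest.approx(0.4)  # mean of 0.2, 0.4, 0.6
    assert mu.loc["cg0", "b"] == pytest.approx(0.8)  # mean of one sample
    assert mu.loc["cg1", "a"] == pytest.approx(0.7 / 3)


def test_reference_means_reject_missing_values():
    values = np.array([[0.2, np.nan], [0.1, 0.3]])
    ref, sheet = _tiny_ref(values, ["a", "b"])
    with pytest.raises(ParameterError, match="cg0"):
        nd.compute_reference_means(ref, sheet, ["cg0", "cg1"])


def test_anova_recovers_planted_sites(atomic_model, reference):
    """With delta 0.4 and noise 0.02 every selected site is a planted DMP of
    an atomic type feeding the selecting fraction."""
    ref, sheet = reference
    panel = nd.get_preset_panel("2")  # NeuNPos + three pure glial fractions
    model = nd.anova_select(ref, sheet, panel, n_per_type=20)
    allowed = atomic_model.all_planted_sites()
    per_fraction = model.provenance["per_fraction_sites"]
    for frac, sites in per_fraction.items():
        # every selected site carries planted signal; none is background
        assert set(sites) <= allowed, frac


def test_anova_site_cap_for_two_fraction_panel(reference):
    ref, sheet = reference
    model = nd.anova_select(ref, sheet, nd.get_preset_panel("3"), n_per_type=100)
    assert model.n_sites <= 200
    assert model.method == "anova"
    assert model.mu.shape == (model.n_sites, 2)


def test_anova_no_signal_raises_selection_error(atomic_model):
    """Two fractions with identical atomic composition cannot be separated."""
    scheme = nd.FractionScheme(
        {"twinA": {"excitatory_upper": 1.0}, "twinB": {"excitatory_upper": 1.0}}
    )
    ref, sheet = nd.sample_reference(
        atomic_model, scheme, n_per_fraction={"twinA": 8, "twinB": 8}, noise_sd=0.02, seed=21
    )
    with pytest.raises(SelectionError):
        nd.anova_select(ref, sheet, nd.PanelSpec("twins", ("twinA", "twinB")))


def test_anova_deterministic_and_order_invariant(reference):
    ref, sheet = reference
    panel = nd.get_preset_panel("1")
    m1 = nd.anova_select(ref, sheet, panel, n_per_type=40)
    shuffled = sheet.sample(frac=1.0, random_state=3).reset_index(drop=True)
    m2 = nd.anova_select(ref, shuffled, panel, n_per_type=40)
    assert m1.site_ids == m2.site_ids
    np.testing.assert_allclose(m1.mu, m2.mu, atol=1e-12)


def test_selected_direction_matches_reference_means(reference):
    """Hyper sites sit above the other fractions' means, hypo below."""
    ref, sheet = reference
    panel = nd.get_preset_panel("1")
    model = nd.anova_select(ref, sheet, panel, n_per_type=20)
    mu = model.mu_frame()
    for k, frac in enumerate(panel.fraction_labels):
        sites = model.provenance["per_fraction_sites"][frac]
        own = mu.loc[sites, frac].to_numpy()
        others = mu.loc[sites].drop(columns=frac).mean(axis=1).to_numpy()
        diff = own - others
        n_half = len(sites) // 2
        assert (diff[:n_half] > 0).all()  # hypermethylated half
        assert (diff[n_half:] < 0).all()  # hypomethylated half


def test_model_json_round_trip(tmp_path, small_model):
    path = tmp_path / "model.json"
    small_model.to_json(path)
    back = nd.DeconvolutionModel.from_json(path)
    assert back.site_ids == small_model.site_ids
    assert back.fraction_labels == small_model.fraction_labels
    np.testing.assert_allclose(back.mu, small_model.mu, atol=1e-12)
    assert back.method == "anova"


def test_idol_requires_more_than_two_cell_types(reference):
    ref, sheet = reference
    with pytest.raises(ApplicabilityError):
        nd.idol_select(ref, sheet, nd.get_preset_panel("3"), seed=0)


def test_idol_deterministic_and_sized(reference):
    ref, sheet = reference
    panel = nd.get_preset_panel("1")
    kw = dict(max_iter=40, library_size=90, seed=77)
    m1 = nd.idol_select(ref, sheet, panel, **kw)
    m2 = nd.idol_select(ref, sheet, panel, **kw)
    assert m1.site_ids == m2.site_ids
    assert m1.n_sites == 90
    assert m1.method == "idol"
    # the optimisation never ends worse than its first incumbent
    assert m1.provenance["best_score"] <= m1.provenance["first_score"]


def test_idol_library_size_capped_by_pool(reference):
    ref, sheet = reference
    with pytest.raises(ParameterError):
        nd.idol_select(
            ref, sheet, nd.get_preset_panel("1"), candidate_per_type=10, library_size=10_000, seed=0
        )


def test_idol_beats_median_random_library(atomic_model, reference):
    """Planted 4-fraction reference: the IDOL library's held-out mixture RMSE
    is no worse than the median of 50 random libraries of equal size."""
    ref, sheet = reference
    panel = nd.get_preset_panel("2")
    lib_size = 80
    model = nd.idol_select(ref, sheet, panel, library_size=lib_size, max_iter=60, seed=5)

    # held-out style evaluation: mixtures from one fresh sample per fraction
    rng = np.random.default_rng(123)
    grid = nd.composition_grid(panel.k).rows
    sub_sheet = sheet[sheet["fraction_label"].isin(panel.fraction_labels)]
    donors = np.column_stack(
        [
            ref.data[rng.choice(sub_sheet.loc[sub_sheet["fraction_label"] == f, "sample_id"])]
            for f in panel.fraction_labels
        ]
    )
    bulk = donors @ grid.T

    def mixture_rmse(site_ids):
        mu = nd.compute_reference_means(ref, sub_sheet, site_ids, panel.fraction_labels).to_numpy()
        pos = [ref.site_ids.index(s) for s in site_ids]
        w = project_many(bulk[pos], mu)
        return float(np.mean(np.sqrt(np.mean((w - grid.T) ** 2, axis=0))))

    idol_rmse = mixture_rmse(model.site_ids)
    # random libraries drawn from the same t-ranked candidate pool
    t_pool = []
    from neurodeconv.selection import t_statistics_one_vs_rest, _rank_order

    values = ref.data.loc[:, list(sub_sheet["sample_id"])].to_numpy()
    labels = sub_sheet["fraction_label"].to_numpy()
    ids = np.asarray(ref.site_ids)
    for frac in panel.fraction_labels:
        t, _ = t_statistics_one_vs_rest(values, labels == frac)
        order = _rank_order(t, np.abs(t), ids)
        t_pool.extend(ids[order[:150]])
        t_pool.extend(ids[order[::-1][:150]])
    t_pool = sorted(set(t_pool))
    random_scores = []
    for _ in range(50):
        lib = list(rng.choice(t_pool, size=lib_size, replace=False))
        random_scores.append(mixture_rmse(lib))
    assert idol_rmse <= np.median(random_scores)
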