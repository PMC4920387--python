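"""Synthetic data generator: ground truth, noise structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from befmix import (
    GeneratorConfig,
    GeneratorError,
    MixtureObservation,
    all_subsets_mmi,
    default_species_pool,
    generate_experiment,
    generate_mmi_dataset,
    generate_trait_response,
    model_average,
    partition_table,
    tripartite_partition,
    true_partition,
    true_relative_yields,
    validate_design,
)
from befmix.simulate import expected_monoculture, species_base_biomass

COMPONENTS = ["net_effect", "tice", "tdce", "dominance"]


def _null_config(**kw):
    return GeneratorConfig(
        complementarity=0.0, dominance=0.0, trait_dependence=0.0, **kw
    )


# ---------------------------------------------------------------------------
# ground-truth relative yields

def test_null_config_truth_is_zero():
    exp = generate_experiment(_null_config(noise_sd=0.0), seed=1)
    assert np.allclose(exp.truth[COMPONENTS], 0.0, atol=1e-10)
    assert np.allclose(exp.truth["ryt"], 1.0, atol=1e-12)
    # and the pipeline sees exactly that
    part = partition_table(exp.table, exp.design)
    assert np.allclose(part[COMPONENTS], 0.0, atol=1e-9)
    assert np.allclose(part["ryt"], 1.0, atol=1e-12)


def test_complementarity_only_truth():
    exp = generate_experiment(
        GeneratorConfig(
            complementarity=0.1, dominance=0.0, trait_dependence=0.0, noise_sd=0.0
        ),
        seed=2,
    )
    assert (exp.truth["tice"] > 0).all()
    assert np.allclose(exp.truth["tdce"], 0.0, atol=1e-10)
    assert np.allclose(exp.truth["dominance"], 0.0, atol=1e-10)


def test_true_tice_arithmetic():
    # delta_c = 0.1, monocultures (100, 200): TICE = S * delta_c * mean M = 30
    config = GeneratorConfig(complementarity=0.1, dominance=0.0, trait_dependence=0.0)
    mus = np.array([100.0, 200.0])
    ry = true_relative_yields(config, mus)
    res = tripartite_partition(
        MixtureObservation(("a", "b"), tuple(mus * ry), tuple(mus))
    )
    assert res.tice == pytest.approx(30.0, abs=1e-9)
    assert res.tdce == pytest.approx(0.0, abs=1e-9)
    assert res.dominance == pytest.approx(0.0, abs=1e-9)


def test_noise_free_pipeline_equals_truth(noise_free_experiment):
    exp = noise_free_experiment
    part = partition_table(exp.table, exp.design)
    merged = part.merge(exp.truth, on="plot_id", suffixes=("", "_true"))
    assert len(merged) == 64
    for comp in COMPONENTS:
        assert np.allclose(merged[comp], merged[f"{comp}_true"], atol=1e-9)


def test_dominance_is_zero_sum():
    # delta_d alone shifts shares without changing RYT
    config = GeneratorConfig(complementarity=0.0, dominance=1.0, trait_dependence=0.0)
    mus = np.array([100.0, 150.0, 300.0, 450.0])
    ry = true_relative_yields(config, mus)
    assert ry.sum() == pytest.approx(1.0, abs=1e-12)
    assert ry[np.argmax(mus)] > 1 / 4 > ry[np.argmin(mus)]


def test_negative_relative_yield_rejected():
    config = GeneratorConfig(complementarity=0.0, dominance=10.0, trait_dependence=0.0)
    with pytest.raises(GeneratorError):
        true_relative_yields(config, np.array([100.0, 900.0]))


# ---------------------------------------------------------------------------
# config validation

@pytest.mark.parametrize(
    "kw",
    [
        {"base_biomass": -1.0},
        {"shade_mult": 0.0},
        {"fert_mult": -2.0},
        {"noise_sd": -0.1},
        {"dominance": -1.0},
        {"complementarity": -0.3},
        {"dropout_rate": 1.0},
        {"stature_effect": 500.0},
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(GeneratorError):
        GeneratorConfig(**kw).validate()


# ---------------------------------------------------------------------------
# generated experiments

def test_generated_design_validates(experiment):
    validate_design(experiment.design, experiment.species)


def test_environment_multipliers_visible_in_one_experiment(experiment):
    """Light check on one seed; tight recovery lives in the acceptance suite."""
    frame = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in experiment.design],
            "shade": [p.environment.shade for p in experiment.design],
            "fertilized": [p.environment.fertilized for p in experiment.design],
        }
    )
    totals = experiment.table.groupby("plot_id")["biomass"].sum()
    frame["total"] = frame["plot_id"].map(totals)
    shade_ratio = frame[frame["shade"]]["total"].mean() / frame[~frame["shade"]]["total"].mean()
    fert_ratio = frame[frame["fertilized"]]["total"].mean() / frame[~frame["fertilized"]]["total"].mean()
    assert 0.66 <= shade_ratio <= 0.86
    assert 1.22 <= fert_ratio <= 1.52


def test_expected_monoculture_multipliers():
    config = GeneratorConfig()
    base = species_base_biomass(default_species_pool(), config)
    # tall grass baseline: 450 + 120 + 30
    assert base["Arr.ela"] == pytest.approx(600.0)
    assert base["Pru.vul"] == pytest.approx(300.0)
    from befmix.design import Environment

    mu0 = expected_monoculture(config, 600.0, Environment(False, False))
    assert expected_monoculture(config, 600.0, Environment(True, False)) == pytest.approx(
        mu0 * 0.76
    )
    assert expected_monoculture(config, 600.0, Environment(False, True)) == pytest.approx(
        mu0 * 1.36
    )


def test_same_seed_byte_identical():
    a = generate_experiment(GeneratorConfig(), seed=99)
    b = generate_experiment(GeneratorConfig(), seed=99)
    assert a.table.to_csv() == b.table.to_csv()
    assert a.truth.to_csv() == b.truth.to_csv()
    assert a.trait_table.to_csv() == b.trait_table.to_csv()
    assert a.design == b.design
    c = generate_experiment(GeneratorConfig(), seed=100)
    assert c.table.to_csv() != a.table.to_csv()


def test_dropout_produces_zero_rows():
    exp = generate_experiment(GeneratorConfig(dropout_rate=0.3), seed=3)
    mixture_plots = {p.plot_id for p in exp.design if p.richness > 1}
    mix_rows = exp.table[exp.table["plot_id"].isin(mixture_plots)]
    assert (mix_rows["biomass"] == 0).sum() > 0
    assert (exp.table["biomass"] >= 0).all()


def test_trait_table_covers_all_cells(experiment):
    tt = experiment.trait_table
    assert len(tt) == 8 * 4 * 6  # species x environments x traits
    assert (tt["value"] > 0).all()
    counts = tt.groupby(["species_id", "environment", "trait"]).size()
    assert (counts == 1).all()


# ---------------------------------------------------------------------------
# trait-response generator

def test_generate_trait_response_recovery():
    data = generate_mmi_dataset(n=62, n_predictors=12, active=(), seed=21)
    cols = [c for c in data.columns if c.startswith("x")]
    response, truth = generate_trait_response(
        data[cols], data["block"], {"x05": 1.2}, noise_sd=0.4, seed=21
    )
    assert truth["x05"] == 1.2 and truth.drop("x05").eq(0).all()
    frame = data[cols + ["block"]].assign(response=response)
    avg = model_average(all_subsets_mmi(frame, "response", cols)).set_index("predictor")
    assert avg.loc["x05", "importance"] > 0.9


def test_generate_trait_response_null_exchangeability():
    """Null responses: no fixed predictor should systematically win.

    Retained-set importance is conditional on retention and can be large
    for a lucky noise predictor in any single replicate, so its level is
    not a useful null diagnostic.  Exchangeability is: with pure-noise
    responses the top-ranked predictor must vary across replicates
    rather than concentrate on one column.
    """
    data = generate_mmi_dataset(n=62, n_predictors=12, active=(), seed=30)
    cols = [c for c in data.columns if c.startswith("x")]
    winners = []
    n_rep = 20
    for rep in range(n_rep):
        response, _ = generate_trait_response(
            data[cols], data["block"], {}, seed=1000 + rep
        )
        frame = data[cols + ["block"]].assign(response=response)
        avg = model_average(all_subsets_mmi(frame, "response", cols)).set_index(
            "predictor"
        )
        winners.append(avg["importance"].idxmax())
    counts = pd.Series(winners).value_counts()
    assert len(counts) >= 4  # many different predictors take the top rank
    assert counts.iloc[0] <= n_rep // 2  # none dominates


def test_generate_trait_response_rank_stability():
    """Doubling the noise SD must not change which predictor dominates."""
    data = generate_mmi_dataset(n=62, n_predictors=8, active=(), seed=31)
    cols = [c for c in data.columns if c.startswith("x")]
    winners = {}
    for sd in (0.5, 1.0):
        importances = np.zeros(len(cols))
        for rep in range(5):
            response, _ = generate_trait_response(
                data[cols], data["block"], {"x03": 1.0}, noise_sd=sd, seed=500 + rep
            )
            frame = data[cols + ["block"]].assign(response=response)
            avg = model_average(all_subsets_mmi(frame, "response", cols))
            imp = avg.set_index("predictor")["importance"]
            importances += imp.reindex(cols).to_numpy()
        winners[sd] = cols[int(np.argmax(importances))]
    assert winners[0.5] == winners[1.0] == "x03"


def test_generate_trait_response_validation():
    data = generate_mmi_dataset(n=30, n_predictors=3, seed=32)
    cols = ["x01", "x02", "x03"]
    with pytest.raises(GeneratorError):
        generate_trait_response(data[cols], data["block"], {"nope": 1.0})
    with pytest.raises(GeneratorError):
        generate_trait_response(data[cols], data["block"][:10], {})


def test_generate_mmi_dataset_validation():
    with pytest.raises(GeneratorError):
        generate_mmi_dataset(n=5)
    with pytest.raises(GeneratorError):
        generate_mmi_dataset(active=(99,))


# ---------------------------------------------------------------------------
# true_partition bookkeeping

def test_true_partition_shape(experiment):
    truth = true_partition(experiment.config, experiment.design, experiment.species)
    assert len(truth) == 64
    assert set(truth["richness"]) == {2, 4}
    # identity holds on the truth as well
    assert np.allclose(
        truth["net_effect"],
        truth["tice"] + truth["tdce"] + truth["dominance"],
        atol=1e-9,
    )
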