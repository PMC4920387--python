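"""Overyielding metrics and the tripartite partition.

The worked examples and the brute-force oracle below were frozen before the
implementation was run against them; the oracle evaluates the partition
directly from the summed-deviation definitions, sharing no code with the
package.
"""

import numpy as np
import pandas as pd
import pytest

from befmix import (
    MixtureObservation,
    PartitionUndefinedError,
    UndefinedRelativeYieldError,
    additive_partition,
    corrected_relative_yield,
    overyield_max,
    overyield_mean,
    partition_table,
    percent_gain_summary,
    relative_yield_total,
    relative_yields,
    tripartite_partition,
)
from conftest import random_mixture


def brute_force_partition(mono, mixed, q=None):
    """Independent oracle: summed-deviation forms of the three components.

    TICE = S * mean(dRY) * mean(M)
    DE   = sum_i (M_i - mean M) * (RY_i/RYT - q_i - mean(RY/RYT - q))
    TDCE = sum_i (M_i - mean M) * (RY_i - RY_i/RYT - mean(RY - RY/RYT))
    written as explicit python loops over species.
    """
    mono = [float(m) for m in mono]
    mixed = [float(y) for y in mixed]
    s = len(mono)
    q = [1.0 / s] * s if q is None else list(q)
    ry = [y / m for y, m in zip(mixed, mono)]
    ryt = sum(ry)
    m_bar = sum(mono) / s
    d_ry = [r - qi for r, qi in zip(ry, q)]
    tice = s * (sum(d_ry) / s) * m_bar

    share_dev = [r / ryt - qi for r, qi in zip(ry, q)]
    share_bar = sum(share_dev) / s
    de = sum((m - m_bar) * (sd - share_bar) for m, sd in zip(mono, share_dev))

    extra = [r - r / ryt for r in ry]
    extra_bar = sum(extra) / s
    tdce = sum((m - m_bar) * (e - extra_bar) for m, e in zip(mono, extra))

    ne = sum(mixed) - sum(qi * m for qi, m in zip(q, mono))
    return ne, tice, tdce, de


# ---------------------------------------------------------------------------
# elementary metrics

def test_relative_yields_basic():
    obs = MixtureObservation(("a", "b"), (60.0, 120.0), (100.0, 200.0))
    assert np.allclose(relative_yields(obs), [0.6, 0.6])


def test_relative_yield_of_monoculture_is_one():
    obs = MixtureObservation(("a",), (250.0,), (250.0,))
    assert np.allclose(relative_yields(obs), [1.0])


def test_relative_yield_of_dead_species_is_zero():
    obs = MixtureObservation(("a", "b"), (0.0, 50.0), (100.0, 100.0))
    assert np.allclose(relative_yields(obs), [0.0, 0.5])


def test_relative_yield_zero_monoculture_errors():
    obs = MixtureObservation(("a", "b"), (10.0, 50.0), (0.0, 100.0))
    with pytest.raises(UndefinedRelativeYieldError, match="'a'"):
        relative_yields(obs)


def test_relative_yield_total():
    assert relative_yield_total([0.6, 0.6]) == pytest.approx(1.2)
    assert relative_yield_total([0.5, 0.5]) == pytest.approx(1.0)
    assert relative_yield_total([0.3, 0.7, 0.2, 0.1]) == pytest.approx(1.3)
    with pytest.raises(ValueError):
        relative_yield_total([])


def test_overyield_mean():
    assert overyield_mean(180.0, 150.0) == pytest.approx(0.2)
    assert overyield_mean(150.0, 150.0) == 0.0
    with pytest.raises(ValueError):
        overyield_mean(100.0, 0.0)


def test_overyield_max():
    assert overyield_max(180.0, [100.0, 200.0]) == pytest.approx(-0.1)
    assert overyield_max(250.0, [100.0, 200.0]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        overyield_max(100.0, [0.0])


def test_corrected_relative_yield():
    assert corrected_relative_yield(0.6, 2) == pytest.approx(1.2)
    assert corrected_relative_yield(0.25, 4) == pytest.approx(1.0)
    assert corrected_relative_yield(0.1, 2) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        corrected_relative_yield(0.5, 0)


# ---------------------------------------------------------------------------
# worked tripartite examples (hand-derived, frozen)

def test_pure_complementarity_example():
    obs = MixtureObservation(("a", "b"), (60.0, 120.0), (100.0, 200.0))
    res = tripartite_partition(obs)
    assert res.net_effect == pytest.approx(30.0, abs=1e-12)
    assert res.tice == pytest.approx(30.0, abs=1e-12)
    assert res.tdce == pytest.approx(0.0, abs=1e-12)
    assert res.dominance == pytest.approx(0.0, abs=1e-12)
    assert res.ryt == pytest.approx(1.2)
    assert res.d_mean == pytest.approx(0.2)


def test_pure_dominance_example():
    # RY = (0.3, 0.7), RYT = 1: share shift with no net RY gain
    obs = MixtureObservation(("a", "b"), (30.0, 140.0), (100.0, 200.0))
    res = tripartite_partition(obs)
    assert res.net_effect == pytest.approx(20.0, abs=1e-12)
    assert res.tice == pytest.approx(0.0, abs=1e-12)
    assert res.tdce == pytest.approx(0.0, abs=1e-12)
    assert res.dominance == pytest.approx(20.0, abs=1e-12)
    ce, se = additive_partition(obs)
    assert ce == pytest.approx(0.0, abs=1e-12)
    assert se == pytest.approx(20.0, abs=1e-12)


def test_mixed_components_example():
    obs = MixtureObservation(("a", "b"), (50.0, 200.0), (100.0, 200.0))
    res = tripartite_partition(obs)
    assert res.net_effect == pytest.approx(100.0, abs=1e-12)
    assert res.tice == pytest.approx(75.0, abs=1e-12)
    assert res.tdce == pytest.approx(25.0 / 3.0, abs=1e-9)
    assert res.dominance == pytest.approx(50.0 / 3.0, abs=1e-9)
    ce, se = additive_partition(obs)
    assert ce == pytest.approx(res.tice, abs=1e-12)
    assert se == pytest.approx(res.tdce + res.dominance, abs=1e-9)


def test_worked_examples_match_brute_force_oracle():
    cases = [
        ((100.0, 200.0), (60.0, 120.0)),
        ((100.0, 200.0), (30.0, 140.0)),
        ((100.0, 200.0), (50.0, 200.0)),
    ]
    for mono, mixed in cases:
        res = tripartite_partition(
            MixtureObservation(("a", "b"), mixed, mono)
        )
        ne, tice, tdce, de = brute_force_partition(mono, mixed)
        assert res.net_effect == pytest.approx(ne, abs=1e-12)
        assert res.tice == pytest.approx(tice, abs=1e-12)
        assert res.tdce == pytest.approx(tdce, abs=1e-10)
        assert res.dominance == pytest.approx(de, abs=1e-10)


# ---------------------------------------------------------------------------
# properties (fuzzed)

def test_partition_identity_and_oracles_fuzzed():
    rng = np.random.default_rng(2024)
    for _ in range(500):
        obs = random_mixture(rng)
        res = tripartite_partition(obs)
        scale = max(1.0, abs(res.net_effect))
        assert abs(res.net_effect - (res.tice + res.tdce + res.dominance)) < 1e-9 * scale
        ce, se = additive_partition(obs)
        assert res.complementarity == pytest.approx(ce, abs=1e-9 * scale)
        assert abs(se - (res.tdce + res.dominance)) < 1e-9 * scale
        ne, tice, tdce, de = brute_force_partition(
            obs.monoculture_biomass, obs.mixture_biomass
        )
        assert res.tice == pytest.approx(tice, rel=1e-9, abs=1e-9 * scale)
        assert res.tdce == pytest.approx(tdce, rel=1e-9, abs=1e-9 * scale)
        assert res.dominance == pytest.approx(de, rel=1e-9, abs=1e-9 * scale)


def test_d_mean_ryt_link_and_d_max_bound():
    """Exact closed form: D_mean - (RYT - 1) = S cov(RY, M) / mean M.

    The shorthand D_mean = RYT - 1 is the special case cov(RY, M) = 0,
    e.g. uniform relative yields or equal monoculture biomasses.
    """
    rng = np.random.default_rng(5)
    for _ in range(200):
        obs = random_mixture(rng)
        res = tripartite_partition(obs)
        m = np.asarray(obs.monoculture_biomass)
        ry = np.asarray(res.relative_yield)
        s = len(m)
        cov = (ry * m).mean() - ry.mean() * m.mean()
        assert res.d_mean - (res.ryt - 1.0) == pytest.approx(
            s * cov / m.mean(), abs=1e-9
        )
        assert res.d_max <= res.d_mean + 1e-12
    # cov(RY, M) = 0 cases: the shorthand is exact
    uniform = MixtureObservation(("a", "b"), (60.0, 120.0), (100.0, 200.0))
    assert tripartite_partition(uniform).d_mean == pytest.approx(0.2)
    equal_m = MixtureObservation(("a", "b", "c"), (70.0, 20.0, 40.0), (100.0,) * 3)
    res = tripartite_partition(equal_m)
    assert res.d_mean == pytest.approx(res.ryt - 1.0, abs=1e-12)


def test_scaling_biomass_scales_components():
    rng = np.random.default_rng(6)
    obs = random_mixture(rng)
    res = tripartite_partition(obs)
    c = 3.7
    scaled = MixtureObservation(
        obs.species,
        tuple(c * y for y in obs.mixture_biomass),
        tuple(c * m for m in obs.monoculture_biomass),
    )
    res_c = tripartite_partition(scaled)
    for attr in ("net_effect", "tice", "tdce", "dominance"):
        assert getattr(res_c, attr) == pytest.approx(c * getattr(res, attr), rel=1e-12)
    for attr in ("ryt", "d_mean", "d_max"):
        assert getattr(res_c, attr) == pytest.approx(getattr(res, attr), rel=1e-12)


def test_constant_share_gives_zero_dominance():
    # RY_i/RYT constant across species (equal shares) -> DE = 0
    obs = MixtureObservation(("a", "b", "c"), (90.0, 45.0, 180.0), (200.0, 100.0, 400.0))
    res = tripartite_partition(obs)
    assert res.dominance == pytest.approx(0.0, abs=1e-10)


def test_all_dead_mixture_raises():
    obs = MixtureObservation(("a", "b"), (0.0, 0.0), (100.0, 200.0))
    with pytest.raises(PartitionUndefinedError):
        tripartite_partition(obs)


def test_unequal_sown_proportions_identity():
    obs = MixtureObservation(
        ("a", "b", "c"), (80.0, 60.0, 30.0), (200.0, 150.0, 90.0),
        sown_proportions=(0.5, 0.3, 0.2),
    )
    res = tripartite_partition(obs)
    assert res.expected_biomass == pytest.approx(0.5 * 200 + 0.3 * 150 + 0.2 * 90)
    assert res.net_effect == pytest.approx(
        res.tice + res.tdce + res.dominance, abs=1e-9
    )


# ---------------------------------------------------------------------------
# table-level driver

def test_partition_table_has_64_mixtures(experiment):
    table = partition_table(experiment.table, experiment.design)
    assert len(table) == 64
    assert table["excluded_reason"].isna().all()
    assert (table["richness"] > 1).all()


def test_partition_table_zero_monoculture_excluded(experiment):
    table = experiment.table.copy()
    design = experiment.design
    # kill one monoculture: all mixtures containing that species in that
    # environment become non-computable, everything else is unaffected
    victim = next(
        p for p in design if p.richness == 1 and p.sown_species[0] == "Dac.glo"
    )
    table.loc[table["plot_id"] == victim.plot_id, "biomass"] = 0.0
    out = partition_table(table, design)
    excluded = out[out["excluded_reason"].notna()]
    expected = {
        p.plot_id
        for p in design
        if p.richness > 1
        and "Dac.glo" in p.sown_species
        and p.environment == victim.environment
    }
    assert set(excluded["plot_id"]) == expected
    assert excluded["excluded_reason"].str.contains("monoculture").all()
    assert out.loc[out["excluded_reason"].isna(), "net_effect"].notna().all()


def test_partition_table_row_order_invariance(experiment):
    shuffled = experiment.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = partition_table(experiment.table, experiment.design)
    b = partition_table(shuffled, experiment.design)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# percent gains

def _gain_frame(rows):
    frame = pd.DataFrame(
        rows,
        columns=["environment", "net_effect", "tice", "tdce", "dominance",
                 "expected_biomass"],
    )
    frame["excluded_reason"] = None
    return frame


def test_percent_gain_zero_group():
    frame = _gain_frame([("F-S-", 0.0, 0.0, 0.0, 0.0, 200.0)] * 3)
    out = percent_gain_summary(frame)
    assert (out[["pct_net_effect", "pct_tice", "pct_tdce", "pct_dominance"]] == 0).all().all()


def test_percent_gain_single_mixture():
    frame = _gain_frame([("F-S-", 30.0, 30.0, 0.0, 0.0, 150.0)])
    out = percent_gain_summary(frame)
    assert out.loc[0, "pct_net_effect"] == pytest.approx(20.0)


def test_percent_gain_conventions_differ():
    frame = _gain_frame(
        [("F-S-", 10.0, 10.0, 0.0, 0.0, 100.0), ("F-S-", 10.0, 10.0, 0.0, 0.0, 400.0)]
    )
    rom = percent_gain_summary(frame, convention="ratio-of-means")
    mor = percent_gain_summary(frame, convention="mean-of-ratios")
    assert rom.loc[0, "pct_net_effect"] == pytest.approx(100 * 20 / 500)
    assert mor.loc[0, "pct_net_effect"] == pytest.approx((10.0 + 2.5) / 2)
    with pytest.raises(ValueError):
        percent_gain_summary(frame, convention="median")


def test_percent_gain_recovers_uniform_gain():
    # every mixture built with the same proportional gain g -> summary = 100 g
    rng = np.random.default_rng(11)
    g = 0.25
    rows = []
    for _ in range(40):
        y_e = float(rng.uniform(100, 500))
        rows.append(("F-S-", g * y_e, g * y_e, 0.0, 0.0, y_e))
    out = percent_gain_summary(_gain_frame(rows))
    assert out.loc[0, "pct_net_effect"] == pytest.approx(100 * g, rel=1e-9)
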