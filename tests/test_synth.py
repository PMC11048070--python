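"""Synthetic population generator: determinism, truth fidelity, validation."""
import numpy as np
import pandas as pd
import pytest

from spondyref import (
    ConfigError,
    InfeasibleTargetError,
    InjectionSpec,
    LEVEL_NAMES,
    PopulationConfig,
    level_metrics,
    sample_flexext,
    sample_population,
)
from spondyref.synth import metrics_to_landmarks


def test_config_validation_lists_offending_fields():
    cfg = PopulationConfig(n_subjects=0, degen_prevalence=1.5)
    cfg.injection.kind = "sideways"
    with pytest.raises(ConfigError) as exc:
        cfg.validate()
    assert {"n_subjects", "degen_prevalence", "injection.kind"} <= set(exc.value.fields)


def test_flexext_range_validation():
    cfg = PopulationConfig()
    cfg.flexext.flexion_da_range = (10.0, 5.0)
    with pytest.raises(ConfigError, match="flexion_da_range"):
        cfg.validate()
    cfg.flexext.flexion_da_range = (20.0, 40.0)   # above extension: degenerate
    with pytest.raises(ConfigError, match="flexext"):
        cfg.validate()


def test_generation_is_deterministic_in_config_and_seed():
    cfg = PopulationConfig(n_subjects=20, seed=77)
    a = sample_population(cfg)
    b = sample_population(PopulationConfig(n_subjects=20, seed=77))
    pd.testing.assert_frame_equal(a.truth, b.truth)
    ma, _ = a.metrics()
    mb, _ = b.metrics()
    pd.testing.assert_frame_equal(ma, mb)
    c = sample_population(PopulationConfig(n_subjects=20, seed=78))
    assert not a.truth["aspo"].equals(c.truth["aspo"])


def test_prevalence_extremes():
    none = sample_population(PopulationConfig(n_subjects=40, seed=1,
                                              degen_prevalence=0.0))
    assert not none.truth["degenerated"].any()
    allp = sample_population(PopulationConfig(n_subjects=40, seed=1,
                                              degen_prevalence=1.0))
    assert allp.truth["degenerated"].all()


def test_normal_metrics_are_gaussian_when_clean():
    from scipy import stats
    pop = sample_population(PopulationConfig(
        n_subjects=4000, seed=2, degen_prevalence=0.0, age_effect_on=False))
    t34 = pop.truth[pop.truth.level_name == "L3L4"]
    assert abs(stats.skew(t34["aspo"])) < 0.1
    assert abs(stats.skew(t34["avg_dh"])) < 0.1
    assert abs(stats.kurtosis(t34["aspo"], fisher=False) - 3) < 0.25


def test_metric_targets_roundtrip_through_landmarks():
    lv = metrics_to_landmarks(dict(adh=40, pdh=20, aspo=10, pspo=-10,
                                   epwr=1.0, hw_ratio=0.6), width=20)
    m = level_metrics(lv)
    assert m.adh == pytest.approx(40, abs=1e-9)
    assert m.pdh == pytest.approx(20, abs=1e-9)
    assert m.aspo == pytest.approx(10, abs=1e-9)
    assert m.pspo == pytest.approx(-10, abs=1e-9)


def test_infeasible_targets_raise():
    with pytest.raises(InfeasibleTargetError):
        metrics_to_landmarks(dict(adh=-150, pdh=30, aspo=0, pspo=0,
                                  epwr=1, hw_ratio=0.6))
    with pytest.raises(InfeasibleTargetError):
        metrics_to_landmarks(dict(adh=30, pdh=30, aspo=-60, pspo=-60,
                                  epwr=1, hw_ratio=0.6))
    with pytest.raises(InfeasibleTargetError):
        metrics_to_landmarks(dict(adh=30, pdh=30, aspo=0, pspo=0,
                                  epwr=-1, hw_ratio=0.6))


def test_full_loop_population_recovers_sampled_method1_metrics():
    """With digitization noise disabled, the measured method-1 metrics equal
    the sampled truth to 1e-9 for every level of every subject."""
    pop = sample_population(PopulationConfig(n_subjects=50, seed=3,
                                             landmark_noise_sd=0.0))
    met, skips = pop.metrics()
    assert len(skips) == 0
    j = met.merge(pop.truth, on=["subject_id", "level_name"],
                  suffixes=("_meas", "_true"))
    for k in ("adh", "pdh", "aspo", "pspo"):
        err = np.abs(j[f"{k}_meas"] - j[f"{k}_true"]).max()
        assert err < 1e-9, k


def test_flag_labels_follow_sensitivity_and_false_positive_rates():
    pop = sample_population(PopulationConfig(n_subjects=3000, seed=4))
    t = pop.truth
    sens = t.loc[t.degenerated, "flagged"].mean()
    fp = t.loc[~t.degenerated, "flagged"].mean()
    assert sens == pytest.approx(0.8, abs=0.03)
    assert fp == pytest.approx(0.05, abs=0.01)


def test_injected_anterolisthesis_is_labeled_and_large():
    cfg = PopulationConfig(n_subjects=400, seed=5, age_effect_on=False,
                           injection=InjectionSpec(kind="anterolisthesis",
                                                   fraction=0.3))
    pop = sample_population(cfg)
    t = pop.truth
    inj = t[t.injected & ~t.degenerated]
    norm = t[~t.injected & ~t.degenerated]
    assert 0.2 < t["injected"].mean() < 0.4
    # slip replaces the resting offset at +3 residual SDs
    assert inj["slip"].min() == inj["slip"].max() > 3 * norm["slip"].std()
    assert inj["aspo"].mean() > norm["aspo"].mean() + 2 * norm["aspo"].std()


def test_flexext_pairing_scale_and_angle_ranges():
    cfg = PopulationConfig(seed=6, age_effect_on=False)
    fe = sample_flexext(cfg, n_subjects=161)
    for exam in ("flexion", "extension"):
        assert len(fe[exam].truth) == 161 * 5
    fx, ex = fe["flexion"].truth, fe["extension"].truth
    # anatomy persists across the two exams
    merged = fx.merge(ex, on=["subject_id", "level_name"], suffixes=("_f", "_e"))
    np.testing.assert_allclose(merged["slip_f"], merged["slip_e"])
    assert (merged["degenerated_f"] == merged["degenerated_e"]).all()
    # exam-specific angles cover the configured wide ranges
    normal_f = fx.loc[~fx.degenerated, "da"]
    normal_e = ex.loc[~ex.degenerated, "da"]
    assert normal_f.min() >= -8 - 1e-9 and normal_f.max() <= 5 + 1e-9
    assert normal_e.min() >= 5 - 1e-9 and normal_e.max() <= 18 + 1e-9
    # flex/ext angle spread far exceeds the neutral side-lying spread
    neutral = sample_population(PopulationConfig(n_subjects=161, seed=6,
                                                 age_effect_on=False))
    pooled = pd.concat([normal_f, normal_e])
    per_level_neutral = neutral.truth.groupby("level_name")["da"].var().mean()
    assert pooled.var() > 2 * per_level_neutral


def test_age_distribution_is_skewed_older_and_affects_disc_height():
    pop = sample_population(PopulationConfig(n_subjects=3000, seed=8))
    ages = np.array([s.age for s in pop.subjects])
    assert np.mean(ages) > 50
    t = pop.truth[~pop.truth.degenerated]
    old = t[t.age > 70]["avg_dh"].mean()
    young = t[t.age < 45]["avg_dh"].mean()
    assert old < young - 1.0   # exponential age loss in %EPW


def test_measurement_variance_matches_empirical_jitter():
    cfg = PopulationConfig(seed=0)
    pop = sample_population(PopulationConfig(n_subjects=400, seed=9,
                                             degen_prevalence=0.0,
                                             age_effect_on=False))
    met, _ = pop.metrics()
    j = met.merge(pop.truth, on=["subject_id", "level_name"],
                  suffixes=("_m", "_t"))
    j34 = j[j.level_name == "L3L4"]
    vm = cfg.measurement_variance("L3L4")
    for k in ("aspo", "pspo", "adh", "avg_dh", "hw_ratio"):
        emp = (j34[f"{k}_m"] - j34[f"{k}_t"]).std()
        assert emp == pytest.approx(np.sqrt(vm[k]), rel=0.15), k
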