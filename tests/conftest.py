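import numpy as np
import pytest

from spondyref import Level, PopulationConfig, VertebraLandmarks
from spondyref.synth import metrics_to_landmarks


@pytest.fixture
def rectangle_level() -> Level:
    """Two stacked axis-aligned rectangles, width 20, body height 12, disc 6.

    The canonical fixture: every height is 30 %EPW, all offsets and angles
    zero, disc area 0.30 EPW², EPWR 1, H/W 0.6.
    """
    return metrics_to_landmarks(
        dict(adh=30, pdh=30, aspo=0, pspo=0, epwr=1.0, hw_ratio=0.6), width=20)


@pytest.fixture
def small_population():
    """A small contaminated neutral-position population (age effect off)."""
    from spondyref import sample_population
    return sample_population(PopulationConfig(n_subjects=300, seed=1234,
                                              age_effect_on=False))


def random_level(rng) -> Level:
    """A random feasible level via the metric-target construction."""
    t = dict(adh=rng.uniform(5, 50), pdh=rng.uniform(5, 50),
             aspo=rng.uniform(-15, 15), pspo=rng.uniform(-15, 15),
             epwr=rng.uniform(0.85, 1.15), hw_ratio=rng.uniform(0.4, 0.8))
    return metrics_to_landmarks(t, width=rng.uniform(15, 60))


def transform_level(level: Level, rotation_deg, translation, scale) -> Level:
    return Level(level.level_name,
                 level.sup.transformed(rotation_deg, translation, scale),
                 level.inf.transformed(rotation_deg, translation, scale),
                 osteo_flag=level.osteo_flag)


def mirror_level(level: Level) -> Level:
    """Reflect about a vertical axis and swap anterior/posterior corner roles."""
    def flip(v: VertebraLandmarks) -> VertebraLandmarks:
        m = np.array([-1.0, 1.0])
        return VertebraLandmarks(v.label, as_pt=v.ps_pt * m, ps_pt=v.as_pt * m,
                                 ai_pt=v.pi_pt * m, pi_pt=v.ai_pt * m)
    return Level(level.level_name, flip(level.sup), flip(level.inf),
                 osteo_flag=level.osteo_flag)
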