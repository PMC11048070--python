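"""Synthetic lumbar landmark populations with known ground truth.

The generator emulates the statistical structure a lateral-radiograph survey
population is assumed to have, so that every downstream stage (geometry,
trimming, reference building, scoring, projection error) can be exercised
against exact truth:

* level-specific Gaussian metrics for normal discs: average disc height
  ~30 %EPW, disc angle graded from slightly kyphotic at L1-L2 to strongly
  lordotic at L5-S1, small sagittal offsets;
* a latent "neutral-zone" resting offset per level (slip `s`) that moves the
  anterior and posterior offsets in opposite directions, plus a vertebra
  size-ratio factor `g` that moves them together — together these reproduce
  the strong negative ASPO/PSPO correlation seen in survey data;
* a linear offset–angle coupling (flatter discs sit more anteriorly), the
  mechanism behind the failure of neutral-position reference data on
  flexion/extension exams;
* a degenerated sub-population (default 30%) with collapsed, variable disc
  heights, altered angles, unstable offsets and imperfect osteophyte/
  sclerosis flags (80% sensitivity, 5% false positives);
* an exponential age effect on standardized disc height, z = b0·exp(b1·age),
  with an age distribution skewed toward older participants;
* optional injected anterolisthesis/retrolisthesis: the slip replaces the
  neutral-zone resting offset with a fixed displacement, expressed in
  residual-SD units of the offset model.

Landmarks are constructed bottom-up (S1 to L1) so each subject has one
coherent spine; all metric targets round-trip through the geometry module to
machine precision for the method-1 metrics.  Generation is a pure function
of (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import metrics_table
from .types import LEVEL_NAMES, LEVEL_PAIRS, Level, Subject, VertebraLandmarks


class ConfigError(ValueError):
    """Invalid generator configuration; .fields lists the offending fields."""

    def __init__(self, problems: dict[str, str]):
        self.fields = sorted(problems)
        super().__init__("invalid config: " +
                         "; ".join(f"{k}: {v}" for k, v in sorted(problems.items())))


class InfeasibleTargetError(ValueError):
    """Metric targets that no landmark quadrilateral can realize."""


DEFAULT_DA_MEANS = {"L1L2": -2.0, "L2L3": 1.5, "L3L4": 5.0, "L4L5": 8.5, "L5S1": 12.0}


@dataclass
class DegenerationEffect:
    """How the degenerated sub-population differs from normal discs.

    Heights collapse (shift in units of the normal avg_dh SD), angles
    flatten and become more variable, the resting offset becomes unstable
    (slip SD multiplier), endplates remodel slightly.  Flags are imperfect.
    """

    height_shift: float = -3.0       # mean avg_dh shift, in avg_dh SDs
    height_shift_sd: float = 1.0     # severity spread, in avg_dh SDs
    da_shift: float = -4.0           # degrees
    da_shift_sd: float = 3.0
    slip_mult: float = 6.0           # degenerative instability of the offsets
    size_shift: float = 0.02         # osteophytic endplate remodelling
    size_sd_mult: float = 2.0
    hw_sd_mult: float = 1.5
    flag_sensitivity: float = 0.8
    flag_fp: float = 0.05


@dataclass
class InjectionSpec:
    """Labeled abnormal-SPO injection: the slip replaces the resting offset."""

    kind: str | None = None          # None | "anterolisthesis" | "retrolisthesis"
    fraction: float = 0.0
    magnitude: float = 3.0           # in residual SDs of the offset model


@dataclass
class FlexExtConfig:
    """Paired wide-angle exam generation (disc angle ranges in degrees)."""

    flexion_da_range: tuple[float, float] = (-8.0, 5.0)
    extension_da_range: tuple[float, float] = (5.0, 18.0)
    degen_prevalence: float = 0.05
    age_mean: float = 40.0
    age_sd: float = 12.0


@dataclass
class PopulationConfig:
    """Study conditions of the synthetic survey population."""

    n_subjects: int = 2000
    seed: int = 0
    position: str = "side-lying"

    # normal-disc metric distributions (per level where dict-valued)
    avg_dh_mean: float = 30.0        # %EPW
    avg_dh_sd: float = 4.0
    da_means: dict = field(default_factory=lambda: dict(DEFAULT_DA_MEANS))  # degrees
    da_sd: float = 3.0
    hw_mean: float = 0.6
    hw_sd: float = 0.05
    width_mean: float = 35.0         # arbitrary units; cancels in all metrics
    width_sd: float = 2.5
    width_cv_within: float = 0.02    # vertebra-to-vertebra within a subject

    #: landmark digitization error, %EPW per coordinate (iid Gaussian); emulates
    #: automated landmark placement noise (~0.2 mm on a 35 mm endplate) and
    #: keeps measured metrics from satisfying exact algebraic identities that
    #: no real measurement satisfies
    landmark_noise_sd: float = 0.6

    # offset generative structure (%EPW)
    slip_sd: float = 1.7             # neutral-zone resting offset
    aspo_noise_sd: float = 0.6
    pspo_noise_sd: float = 0.8
    aspo_da_coef: float = -0.20      # per unit of (adh - pdh) deviation
    pspo_da_coef: float = 0.14
    size_ratio_sd: float = 0.015     # SD of vertebra size ratio g

    # contamination and labels
    degen_prevalence: float = 0.3
    degeneration: DegenerationEffect = field(default_factory=DegenerationEffect)
    injection: InjectionSpec = field(default_factory=InjectionSpec)

    # age / demographics (survey-like: older ages over-represented)
    age_effect_on: bool = True
    age_b0: float = -0.0037
    age_b1: float = 0.078
    male_fraction: float = 0.618
    age_male: tuple[float, float] = (50.9, 15.3)
    age_female: tuple[float, float] = (63.3, 6.4)
    age_range: tuple[float, float] = (25.0, 90.0)
    bmi_male: tuple[float, float] = (25.5, 4.0)
    bmi_female: tuple[float, float] = (26.4, 5.5)

    # back-pain outcome model (odds ratios per unit of the spine summaries)
    pain_base_rate: float = 0.181
    pain_or_pstsi: float = 1.14
    pain_or_min_zavgdh: float = 0.80

    flexext: FlexExtConfig = field(default_factory=FlexExtConfig)

    def validate(self) -> None:
        bad: dict[str, str] = {}
        if self.n_subjects < 1:
            bad["n_subjects"] = "must be >= 1"
        for name in ("avg_dh_sd", "da_sd", "hw_sd", "width_sd", "slip_sd",
                     "aspo_noise_sd", "pspo_noise_sd", "size_ratio_sd",
                     "landmark_noise_sd"):
            if getattr(self, name) < 0:
                bad[name] = "sd must be >= 0"
        for name in ("degen_prevalence", "pain_base_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad[name] = "probability must be in [0, 1]"
        d = self.degeneration
        for name in ("flag_sensitivity", "flag_fp"):
            v = getattr(d, name)
            if not 0.0 <= v <= 1.0:
                bad[f"degeneration.{name}"] = "probability must be in [0, 1]"
        inj = self.injection
        if inj.kind not in (None, "anterolisthesis", "retrolisthesis"):
            bad["injection.kind"] = f"unknown kind {inj.kind!r}"
        if not 0.0 <= inj.fraction <= 1.0:
            bad["injection.fraction"] = "must be in [0, 1]"
        if set(self.da_means) != set(LEVEL_NAMES):
            bad["da_means"] = f"must have exactly the keys {LEVEL_NAMES}"
        fe = self.flexext
        for rng_name in ("flexion_da_range", "extension_da_range"):
            lo, hi = getattr(fe, rng_name)
            if not lo < hi:
                bad[f"flexext.{rng_name}"] = "range must satisfy lo < hi"
        if not bad:
            f_lo, f_hi = fe.flexion_da_range
            e_lo, e_hi = fe.extension_da_range
            if (f_lo + f_hi) / 2 >= (e_lo + e_hi) / 2:
                bad["flexext"] = "flexion range must sit below the extension range"
        if bad:
            raise ConfigError(bad)

    # ------------------------------------------------------------------
    def residual_sd(self, target: str, level_name: str = "L3L4") -> float:
        """SD of the offset-model residual (slip + metric noise + landmark
        measurement error), %EPW."""
        noise = self.aspo_noise_sd if target == "aspo" else self.pspo_noise_sd
        var_meas = self.measurement_variance(level_name)[target]
        return math.sqrt(self.slip_sd**2 + noise**2 + var_meas)

    def measurement_variance(self, level_name: str) -> dict[str, float]:
        """First-order variance of each metric under landmark jitter.

        Exact delta-method propagation: the Jacobian of every metric with
        respect to the 16 corner coordinates is evaluated (finite
        differences) at the level's mean geometry, and the iid per-coordinate
        jitter variance is pushed through.  Cached per level.
        """
        cache = getattr(self, "_meas_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_meas_cache", cache)
        key = (level_name, self.landmark_noise_sd)
        if key in cache:
            return cache[key]
        from .geometry import level_metrics  # local import to avoid a cycle
        from .types import METRIC_COLUMNS, Level

        t = math.tan(math.radians(self.da_means[level_name]))
        delta = 100.0 * t
        base = {"adh": self.avg_dh_mean + delta / 2.0,
                "pdh": self.avg_dh_mean - delta / 2.0,
                "aspo": 0.0, "pspo": 0.0, "epwr": 1.0, "hw_ratio": self.hw_mean}
        level = metrics_to_landmarks(base, width=100.0, level_name=level_name)
        m0 = level_metrics(level)
        nu = self.landmark_noise_sd          # jitter sd in coordinate units (W=100)
        step = 1e-4
        var = {m: 0.0 for m in METRIC_COLUMNS}
        for which in ("sup", "inf"):
            v0 = getattr(level, which)
            for ci in range(4):
                for xy in range(2):
                    pts = v0.corners.copy()
                    pts[ci, xy] += step
                    v1 = VertebraLandmarks(v0.label, *pts)
                    lv1 = Level(level_name, v1 if which == "sup" else level.sup,
                                level.inf if which == "sup" else v1)
                    m1 = level_metrics(lv1)
                    for m in METRIC_COLUMNS:
                        g = (getattr(m1, m) - getattr(m0, m)) / step
                        var[m] += (g * nu) ** 2
        cache[key] = var
        return var

    def normal_params(self, level_name: str, metric: str) -> tuple[float, float]:
        """Analytic (mean, sd) of a metric among normal discs, age effect off.

        First-order delta-method linearizations; used as the known truth in
        parameter-recovery checks.
        """
        m_da = self.da_means[level_name]
        t = math.tan(math.radians(m_da))
        sd_delta = 100.0 * (1.0 + t * t) * math.radians(self.da_sd)
        delta_bar = 100.0 * t
        var_sum_noise = self.aspo_noise_sd**2 + self.pspo_noise_sd**2
        sum_coef = self.aspo_da_coef + self.pspo_da_coef
        vm = self.measurement_variance(level_name)  # landmark-jitter propagation
        if metric == "avg_dh":
            return self.avg_dh_mean, math.sqrt(self.avg_dh_sd**2 + vm["avg_dh"])
        if metric == "da":
            return m_da, math.sqrt(self.da_sd**2 + vm["da"])
        if metric == "aspo":
            sd = math.sqrt((50.0 * self.size_ratio_sd)**2 + self.slip_sd**2
                           + (self.aspo_da_coef * sd_delta)**2
                           + self.aspo_noise_sd**2 + vm["aspo"])
            return 0.0, sd
        if metric == "pspo":
            sd = math.sqrt((50.0 * self.size_ratio_sd)**2 + self.slip_sd**2
                           + (self.pspo_da_coef * sd_delta)**2
                           + self.pspo_noise_sd**2 + vm["pspo"])
            return 0.0, sd
        if metric == "epwr":
            # epwr = sqrt((1 + (aspo+pspo)/100)^2 + ((adh-pdh)/100)^2)
            mu = 1.0 + (delta_bar**2 + sd_delta**2) / 2.0e4
            var = (self.size_ratio_sd**2
                   + (sum_coef * sd_delta / 100.0)**2
                   + var_sum_noise / 1.0e4
                   + (delta_bar * sd_delta / 1.0e4)**2
                   + vm["epwr"])
            return mu, math.sqrt(var)
        if metric == "hw_ratio":
            return self.hw_mean, math.sqrt(self.hw_sd**2 + vm["hw_ratio"])
        if metric == "disc_area":
            # exact shoelace expansion: area = avg/100·(1 + (aspo+pspo)/200)
            #                                  + (adh−pdh)(pspo−aspo)/4e4
            dif_coef = self.pspo_da_coef - self.aspo_da_coef
            mu = self.avg_dh_mean / 100.0 + dif_coef * sd_delta**2 / 4.0e4
            sd_ap = math.sqrt((100.0 * self.size_ratio_sd)**2
                              + (sum_coef * sd_delta)**2 + var_sum_noise)
            sd_pma = math.sqrt(4.0 * self.slip_sd**2 + (dif_coef * sd_delta)**2
                               + var_sum_noise)
            var = (self.avg_dh_sd / 100.0)**2 \
                + (self.avg_dh_mean / 100.0 * sd_ap / 200.0)**2 \
                + (math.hypot(delta_bar, sd_delta) * sd_pma / 4.0e4)**2 \
                + vm["disc_area"]
            return mu, math.sqrt(var)
        raise KeyError(f"no analytic normal parameters for metric {metric!r}")


# ---------------------------------------------------------------------------
# landmark construction

def _unit2(v):
    n = math.hypot(v[0], v[1])
    return np.array([v[0] / n, v[1] / n])


def _build_on_base(a_pt, p_pt, label, adh, pdh, aspo, pspo, w_top, hw):
    """Place a superior vertebra on the endplate segment (a_pt anterior,
    p_pt posterior) so method-1 metrics reproduce the targets exactly."""
    a_pt, p_pt = np.asarray(a_pt, float), np.asarray(p_pt, float)
    w = math.hypot(*(a_pt - p_pt))
    u = _unit2(a_pt - p_pt)
    n = np.array([-u[1], u[0]])
    ai = a_pt + u * (aspo * w / 100.0) + n * (adh * w / 100.0)
    pi = p_pt - u * (pspo * w / 100.0) + n * (pdh * w / 100.0)
    w_inf = math.hypot(*(ai - pi))
    if w_inf < 1e-9 * w or (100.0 + aspo + pspo) <= 1.0:
        raise InfeasibleTargetError(
            f"offsets aspo={aspo:.3g}, pspo={pspo:.3g} collapse the endplate")
    if adh <= -100.0 or pdh <= -100.0:
        raise InfeasibleTargetError(f"disc heights adh={adh:.3g}, pdh={pdh:.3g} infeasible")
    if w_top <= 0 or hw <= 0:
        raise InfeasibleTargetError(f"w_top={w_top:.3g} and hw={hw:.3g} must be > 0")
    u2 = _unit2(ai - pi)
    n2 = np.array([-u2[1], u2[0]])
    mid = (ai + pi) / 2.0
    h = hw * (w_inf + w_top) / 2.0
    as_ = mid + u2 * (w_top / 2.0) + n2 * h
    ps_ = mid - u2 * (w_top / 2.0) + n2 * h
    return VertebraLandmarks(label, as_, ps_, ai, pi)


def metrics_to_landmarks(targets: dict, width: float = 35.0,
                         level_name: str = "L3L4") -> Level:
    """Build a two-vertebra level whose measured method-1 metrics equal the
    targets {adh, pdh, aspo, pspo, epwr, hw_ratio} exactly.

    The inferior vertebra is a rectangle of width `width`; `epwr` sizes the
    superior vertebra's top endplate and `hw_ratio` its wall height.  EPWR
    and the height/width ratio as *measured* emerge from the construction
    (the same corners encode both the offsets and the endplate width, so
    they cannot all be set independently).
    """
    if width <= 0:
        raise InfeasibleTargetError("width must be > 0")
    for key in ("adh", "pdh", "aspo", "pspo", "epwr", "hw_ratio"):
        if key not in targets:
            raise KeyError(f"targets missing {key!r}")
    sup_lbl, inf_lbl = LEVEL_PAIRS[level_name]
    a_pt = np.array([width / 2.0, 0.0])
    p_pt = np.array([-width / 2.0, 0.0])
    body = targets["hw_ratio"] * width
    inf = VertebraLandmarks(inf_lbl, a_pt, p_pt,
                            a_pt - (0.0, body), p_pt - (0.0, body))
    sup = _build_on_base(a_pt, p_pt, sup_lbl,
                         targets["adh"], targets["pdh"],
                         targets["aspo"], targets["pspo"],
                         w_top=targets["epwr"] * width, hw=targets["hw_ratio"])
    return Level(level_name, sup, inf)


# ---------------------------------------------------------------------------
# population sampling

@dataclass
class SyntheticPopulation:
    """Subjects with landmarks plus the per-level generative truth table."""

    subjects: list[Subject]
    truth: pd.DataFrame
    config: PopulationConfig

    def metrics(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Measured per-level metrics via the geometry module."""
        return metrics_table(self.subjects)

    @property
    def labels(self) -> pd.DataFrame:
        return self.truth[["subject_id", "level_name",
                           "degenerated", "flagged", "injected"]]


def _draw_demographics(cfg: PopulationConfig, rng) -> tuple[str, float, float]:
    male = rng.random() < cfg.male_fraction
    mu, sd = cfg.age_male if male else cfg.age_female
    age = float(np.clip(rng.normal(mu, sd), *cfg.age_range))
    bmu, bsd = cfg.bmi_male if male else cfg.bmi_female
    bmi = float(np.clip(rng.normal(bmu, bsd), 15.0, 55.0))
    return ("M" if male else "F"), age, bmi


def _level_latents(cfg: PopulationConfig, rng, degen: bool, injected: bool):
    """Draw the persistent (posture-independent) latents of one level."""
    d = cfg.degeneration
    avg_shift = 0.0
    if degen:
        avg_shift = cfg.avg_dh_sd * rng.normal(d.height_shift, d.height_shift_sd)
    g = rng.normal(1.0 + (d.size_shift if degen else 0.0),
                   cfg.size_ratio_sd * (d.size_sd_mult if degen else 1.0))
    hw = rng.normal(cfg.hw_mean, cfg.hw_sd * (d.hw_sd_mult if degen else 1.0))
    hw = float(np.clip(hw, 0.2, 1.5))
    if injected:
        inj = cfg.injection
        mag = inj.magnitude * cfg.residual_sd(
            "aspo" if inj.kind == "anterolisthesis" else "pspo")
        slip = mag if inj.kind == "anterolisthesis" else -mag
    else:
        slip = rng.normal(0.0, cfg.slip_sd * (d.slip_mult if degen else 1.0))
    avg_base = rng.normal(cfg.avg_dh_mean, cfg.avg_dh_sd) + avg_shift
    return avg_base, g, hw, slip


def _realize_exam(cfg: PopulationConfig, rng, level_name: str, latents, degen: bool,
                  da: float, age_z: float):
    """Turn persistent latents + an exam-specific disc angle into metric
    targets; returns the target dict plus the posterior-offset deviation."""
    avg_base, g, hw, slip = latents
    delta0 = 100.0 * math.tan(math.radians(da))
    delta_bar = 100.0 * math.tan(math.radians(cfg.da_means[level_name]))
    dc = delta0 - delta_bar
    eps_a = rng.normal(0.0, cfg.aspo_noise_sd)
    eps_p = rng.normal(0.0, cfg.pspo_noise_sd)
    aspo = 50.0 * (g - 1.0) + slip + cfg.aspo_da_coef * dc + eps_a
    pspo = 50.0 * (g - 1.0) - slip + cfg.pspo_da_coef * dc + eps_p
    delta = math.tan(math.radians(da)) * (100.0 + aspo + pspo)
    avg = avg_base + cfg.avg_dh_sd * age_z
    avg = max(avg, abs(delta) / 2.0 + 1.0)      # floor: collapsed but not inverted
    adh, pdh = avg + delta / 2.0, avg - delta / 2.0
    targets = {"adh": adh, "pdh": pdh, "aspo": aspo, "pspo": pspo,
               "epwr": g, "hw_ratio": hw}
    pst_dev = -slip + eps_p                      # deviation from the offset model
    return targets, avg, pst_dev


def _spine_from_targets(cfg: PopulationConfig, rng, per_level: dict[str, dict],
                        flags: dict[str, bool]) -> list[Level]:
    """Stack a coherent spine bottom-up (S1 → L1) from per-level targets."""
    widths = {}
    base_w = max(5.0, rng.normal(cfg.width_mean, cfg.width_sd))
    for v in ("S1", "L5", "L4", "L3", "L2", "L1"):
        widths[v] = base_w * max(0.5, rng.normal(1.0, cfg.width_cv_within))
    # S1: rectangle below its superior endplate
    w = widths["S1"]
    a_pt, p_pt = np.array([w / 2.0, 0.0]), np.array([-w / 2.0, 0.0])
    body = cfg.hw_mean * w
    verts = {"S1": VertebraLandmarks("S1", a_pt, p_pt,
                                     a_pt - (0.0, body), p_pt - (0.0, body))}
    for name in reversed(LEVEL_NAMES):          # L5S1 first
        sup_lbl, inf_lbl = LEVEL_PAIRS[name]
        t = per_level[name]
        base = verts[inf_lbl]
        sup = _build_on_base(base.as_pt, base.ps_pt, sup_lbl,
                             t["adh"], t["pdh"], t["aspo"], t["pspo"],
                             w_top=widths[sup_lbl], hw=t["hw_ratio"])
        verts[sup_lbl] = sup
    if cfg.landmark_noise_sd > 0:
        # digitization error: iid jitter per corner coordinate, after the
        # exact construction (the truth table keeps the noise-free targets)
        nu = cfg.landmark_noise_sd / 100.0 * base_w
        verts = {lbl: VertebraLandmarks(lbl, *(v.corners + rng.normal(0.0, nu, (4, 2))))
                 for lbl, v in verts.items()}
    return [Level(name, verts[LEVEL_PAIRS[name][0]], verts[LEVEL_PAIRS[name][1]],
                  osteo_flag=flags[name]) for name in LEVEL_NAMES]


def sample_population(config: PopulationConfig | None = None,
                      seed: int | None = None) -> SyntheticPopulation:
    """Draw a full survey-style population (one neutral exam per subject)."""
    cfg = config or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d = cfg.degeneration
    subjects, rows, pain_covariates = [], [], []
    for i in range(cfg.n_subjects):
        sid = f"S{i:05d}"
        sex, age, bmi = _draw_demographics(cfg, rng)
        age_z = cfg.age_b0 * math.exp(cfg.age_b1 * age) if cfg.age_effect_on else 0.0
        per_level, flags = {}, {}
        pst_devs, min_z = [], np.inf
        for name in LEVEL_NAMES:
            degen = rng.random() < cfg.degen_prevalence
            injected = (cfg.injection.kind is not None
                        and rng.random() < cfg.injection.fraction)
            latents = _level_latents(cfg, rng, degen, injected)
            da = rng.normal(cfg.da_means[name], cfg.da_sd)
            if degen:
                da += rng.normal(d.da_shift, d.da_shift_sd)
            targets, avg, pst_dev = _realize_exam(cfg, rng, name, latents, degen,
                                                  da, age_z)
            flag = rng.random() < (d.flag_sensitivity if degen else d.flag_fp)
            per_level[name] = targets
            flags[name] = flag
            pst_devs.append(pst_dev / cfg.residual_sd("pspo"))
            min_z = min(min_z, (avg - cfg.avg_dh_mean) / cfg.avg_dh_sd)
            rows.append({"subject_id": sid, "level_name": name,
                         "position": cfg.position,
                         **targets, "avg_dh": avg, "da": da,
                         "slip": latents[3], "size_ratio": latents[1],
                         "degenerated": degen, "flagged": flag,
                         "injected": injected, "age": age})
        pain_covariates.append((max(pst_devs), min_z))
        levels = _spine_from_targets(cfg, rng, per_level, flags)
        subjects.append(Subject(sid, age=age, sex=sex, bmi=bmi, back_pain=None,
                                position=cfg.position, levels=levels))
    # back pain: logistic in the spine summaries, covariates centered at
    # their population means so pain_base_rate is the realized base rate
    cov = np.asarray(pain_covariates)
    centered = cov - cov.mean(axis=0)
    logit = (math.log(cfg.pain_base_rate / (1.0 - cfg.pain_base_rate))
             + math.log(cfg.pain_or_pstsi) * centered[:, 0]
             + math.log(cfg.pain_or_min_zavgdh) * centered[:, 1])
    pains = rng.random(len(subjects)) < 1.0 / (1.0 + np.exp(-logit))
    for s, p in zip(subjects, pains):
        s.back_pain = bool(p)
    return SyntheticPopulation(subjects, pd.DataFrame(rows), cfg)


def sample_flexext(config: PopulationConfig | None = None, n_subjects: int = 161,
                   seed: int | None = None) -> dict[str, SyntheticPopulation]:
    """Paired flexion and extension exams for asymptomatic-style volunteers.

    Anatomy (slip, size ratio, wall height, base disc height, degeneration)
    persists across the two exams of a subject; the disc angle is drawn
    uniformly from the wide exam-specific range, and metric noise is
    exam-specific.  Returns {"flexion": ..., "extension": ...}.
    """
    cfg = config or PopulationConfig()
    cfg.validate()
    fe = cfg.flexext
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d = cfg.degeneration
    out = {"flexion": ([], []), "extension": ([], [])}
    for i in range(n_subjects):
        sid = f"F{i:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.clip(rng.normal(fe.age_mean, fe.age_sd), 20.0, 75.0))
        bmi = float(np.clip(rng.normal(25.0, 4.0), 15.0, 55.0))
        age_z = cfg.age_b0 * math.exp(cfg.age_b1 * age) if cfg.age_effect_on else 0.0
        shared = {}
        for name in LEVEL_NAMES:
            degen = rng.random() < fe.degen_prevalence
            injected = (cfg.injection.kind is not None
                        and rng.random() < cfg.injection.fraction)
            shared[name] = (degen, injected,
                            _level_latents(cfg, rng, degen, injected))
        for exam, (lo, hi) in (("flexion", fe.flexion_da_range),
                               ("extension", fe.extension_da_range)):
            per_level, flags = {}, {}
            for name in LEVEL_NAMES:
                degen, injected, latents = shared[name]
                da = rng.uniform(lo, hi)
                if degen:
                    da += rng.normal(d.da_shift, d.da_shift_sd)
                targets, avg, _ = _realize_exam(cfg, rng, name, latents, degen,
                                                da, age_z)
                flag = rng.random() < (d.flag_sensitivity if degen else d.flag_fp)
                per_level[name] = targets
                flags[name] = flag
                out[exam][1].append({"subject_id": sid, "level_name": name,
                                     "position": exam, **targets, "avg_dh": avg,
                                     "da": da, "slip": latents[3],
                                     "size_ratio": latents[1],
                                     "degenerated": degen, "flagged": flag,
                                     "injected": injected, "age": age})
            levels = _spine_from_targets(cfg, rng, per_level, flags)
            out[exam][0].append(Subject(sid, age=age, sex=sex, bmi=bmi,
                                        back_pain=None, position=exam,
                                        levels=levels))
    return {exam: SyntheticPopulation(subs, pd.DataFrame(rows), cfg)
            for exam, (subs, rows) in out.items()}
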