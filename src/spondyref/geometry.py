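"""Sagittal disc and offset metrics from four-corner vertebral landmarks.

Two measurement constructions are implemented:

* method 1 (endplate-based): anterior/posterior disc heights are perpendicular
  distances from the inferior corners of the superior vertebra to the line
  through the superior endplate of the inferior vertebra; ASPO/PSPO are
  offsets of matching corners along that endplate line; the disc angle (DA)
  is the angle between the facing endplate lines.
* method 2 (midplane-based, after Frobin): vertebral midplanes join the
  anterior- and posterior-wall midpoints; the bisectrix bisects the midplane
  angle; ventral/dorsal disc heights are summed perpendicular distances of
  the facing corners to the bisectrix; CSPO is the offset between vertebral
  centroids measured along the bisectrix; MPA is the midplane angle.

All lengths are normalized by W, the superior-endplate width of the inferior
vertebra, and reported in %EPW; angles in degrees.  Sign conventions:
positive ASPO = anterior corner of the superior vertebra anterior to the
matching corner below; positive PSPO = posterior corner posterior to the
matching corner below; DA and MPA are negative when the anterior/ventral
height is smaller than the posterior/dorsal one; positive CSPO = superior
centroid anterior.  Every metric is invariant to rigid motions and uniform
scaling of the landmarks.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .types import (
    DegenerateGeometryError,
    Level,
    METRIC_COLUMNS,
    Subject,
    VertebraLandmarks,
)

_EPS = 1e-12
_PARALLEL_TOL = 1e-6  # radians; below this, midplanes are treated as parallel


@dataclass
class LevelMetrics:
    """The nine offset/disc metrics plus composites for one level."""

    adh: float
    pdh: float
    avg_dh: float
    da: float
    aspo: float
    pspo: float
    vdh: float
    ddh: float
    mpa: float
    cspo: float
    disc_area: float
    epwr: float
    hw_ratio: float
    self_intersecting: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# small vectorized helpers; every point array has shape (..., 2)

def _dot(a, b):
    return a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]


def _cross(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _norm(a):
    return np.hypot(a[..., 0], a[..., 1])


def _unit(a, what="direction"):
    n = _norm(a)
    if np.any(n < _EPS):
        raise DegenerateGeometryError(f"degenerate {what}: zero length")
    return a / n[..., None]


def _perp(a):
    """Rotate by +90 deg: for a pointing anterior (+x), result points cephalad."""
    return np.stack([-a[..., 1], a[..., 0]], axis=-1)


def _signed_angle_deg(u_from, u_to):
    return np.degrees(np.arctan2(_cross(u_from, u_to), _dot(u_from, u_to)))


def _segments_intersect(p1, p2, q1, q2):
    """Proper-crossing test for segments p1p2 and q1q2 (vectorized)."""
    d1 = _cross(q2 - q1, p1 - q1)
    d2 = _cross(q2 - q1, p2 - q1)
    d3 = _cross(p2 - p1, q1 - p1)
    d4 = _cross(p2 - p1, q2 - p1)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


# ---------------------------------------------------------------------------
# scalar spec-level operations

def endplate_width(v: VertebraLandmarks, which: str) -> float:
    """Euclidean width of the named endplate ("superior" or "inferior")."""
    if which == "superior":
        a, b = v.as_pt, v.ps_pt
    elif which == "inferior":
        a, b = v.ai_pt, v.pi_pt
    else:
        raise ValueError(f"which must be 'superior' or 'inferior', got {which!r}")
    w = float(np.hypot(*(a - b)))
    if w < _EPS:
        raise DegenerateGeometryError(f"{v.label} {which} endplate has zero width")
    return w


def vertebral_midplane(v: VertebraLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Line through the anterior- and posterior-wall midpoints.

    Returns (point, unit direction), direction oriented posterior→anterior.
    """
    ant = (v.as_pt + v.ai_pt) / 2.0
    post = (v.ps_pt + v.pi_pt) / 2.0
    d = _unit(ant - post, f"{v.label} midplane (coincident wall midpoints)")
    return post, d


def bisectrix(m_sup: tuple[np.ndarray, np.ndarray],
              m_inf: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Angle bisector of two midplane lines, each given as (point, unit dir).

    Of the two bisectors the one whose direction is the normalized mean of the
    two (consistently posterior→anterior) directions is returned.  For
    near-parallel midplanes the line parallel to both, midway between them,
    is returned instead (the intersection point is numerically unstable).
    """
    (p_s, d_s), (p_i, d_i) = m_sup, m_inf
    ang = np.arctan2(abs(_cross(d_s, d_i)), _dot(d_s, d_i))
    d = _unit(d_s + d_i, "bisectrix")
    if ang < _PARALLEL_TOL:
        # midway parallel line; anchors are comparable (posterior-wall) points
        mid = (p_s + p_i) / 2.0
        return mid, d
    t = _cross(p_i - p_s, d_i) / _cross(d_s, d_i)
    x = p_s + t * d_s
    return x, d


# ---------------------------------------------------------------------------
# vectorized metric core

#: corner keys of the batched representation; each maps to an (n, 2) array
CORNER_KEYS = ("sup_as", "sup_ps", "sup_ai", "sup_pi",
               "inf_as", "inf_ps", "inf_ai", "inf_pi")


def metrics_from_arrays(c: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Compute all thirteen metrics for a batch of levels.

    `c` maps each of CORNER_KEYS to an (n, 2) float array.  Returns a dict of
    (n,) arrays keyed by METRIC_COLUMNS plus a boolean "self_intersecting".
    """
    sup_as, sup_ps = c["sup_as"], c["sup_ps"]
    sup_ai, sup_pi = c["sup_ai"], c["sup_pi"]
    inf_as, inf_ps = c["inf_as"], c["inf_ps"]
    inf_ai, inf_pi = c["inf_ai"], c["inf_pi"]

    w_vec = inf_as - inf_ps
    W = _norm(w_vec)
    if np.any(W < _EPS):
        raise DegenerateGeometryError("zero-width superior endplate on inferior vertebra")
    u = w_vec / W[..., None]          # along-endplate, posterior→anterior
    n_hat = _perp(u)                  # off-endplate, cephalad for upright spines

    # --- method 1
    adh = _dot(sup_ai - inf_ps, n_hat) / W * 100.0
    pdh = _dot(sup_pi - inf_ps, n_hat) / W * 100.0
    aspo = _dot(sup_ai - inf_as, u) / W * 100.0
    pspo = -_dot(sup_pi - inf_ps, u) / W * 100.0
    u_sup = _unit(sup_ai - sup_pi, "inferior endplate of superior vertebra")
    da = _signed_angle_deg(u, u_sup)

    # --- method 2
    ant_s, post_s = (sup_as + sup_ai) / 2.0, (sup_ps + sup_pi) / 2.0
    ant_i, post_i = (inf_as + inf_ai) / 2.0, (inf_ps + inf_pi) / 2.0
    d_s = _unit(ant_s - post_s, "superior midplane")
    d_i = _unit(ant_i - post_i, "inferior midplane")
    mpa = _signed_angle_deg(d_i, d_s)

    d_b = _unit(d_s + d_i, "bisectrix")
    cross_di = _cross(d_s, d_i)
    parallel = np.abs(np.deg2rad(mpa)) < _PARALLEL_TOL
    # intersection point (guard the parallel rows, then overwrite them)
    denom = np.where(parallel, 1.0, cross_di)
    t = _cross(post_i - post_s, d_i) / denom
    pt = post_s + t[..., None] * d_s
    mid = (post_s + post_i) / 2.0
    pt = np.where(parallel[..., None], mid, pt)

    n_b = _perp(d_b)
    vdh = (np.abs(_dot(sup_ai - pt, n_b)) + np.abs(_dot(inf_as - pt, n_b))) / W * 100.0
    ddh = (np.abs(_dot(sup_pi - pt, n_b)) + np.abs(_dot(inf_ps - pt, n_b))) / W * 100.0

    cen_s = (sup_as + sup_ps + sup_ai + sup_pi) / 4.0
    cen_i = (inf_as + inf_ps + inf_ai + inf_pi) / 4.0
    cspo = _dot(cen_s - cen_i, d_b) / W * 100.0

    # --- composites
    avg_dh = (adh + pdh) / 2.0
    quad = [sup_ai, sup_pi, inf_ps, inf_as]
    area2 = np.zeros_like(W)
    for k in range(4):
        p, q = quad[k], quad[(k + 1) % 4]
        area2 += _cross(p, q)
    disc_area = np.abs(area2) / 2.0 / W**2
    self_x = (_segments_intersect(sup_ai, sup_pi, inf_ps, inf_as)
              | _segments_intersect(sup_pi, inf_ps, inf_as, sup_ai))

    w_sup_inf = _norm(sup_ai - sup_pi)
    epwr = w_sup_inf / W
    wall = (_norm(sup_as - sup_ai) + _norm(sup_ps - sup_pi)) / 2.0
    width = (_norm(sup_as - sup_ps) + w_sup_inf) / 2.0
    hw_ratio = wall / width

    return {
        "adh": adh, "pdh": pdh, "avg_dh": avg_dh, "da": da,
        "aspo": aspo, "pspo": pspo,
        "vdh": vdh, "ddh": ddh, "mpa": mpa, "cspo": cspo,
        "disc_area": disc_area, "epwr": epwr, "hw_ratio": hw_ratio,
        "self_intersecting": self_x,
    }


def _level_arrays(level: Level) -> dict[str, np.ndarray]:
    return {
        "sup_as": level.sup.as_pt[None], "sup_ps": level.sup.ps_pt[None],
        "sup_ai": level.sup.ai_pt[None], "sup_pi": level.sup.pi_pt[None],
        "inf_as": level.inf.as_pt[None], "inf_ps": level.inf.ps_pt[None],
        "inf_ai": level.inf.ai_pt[None], "inf_pi": level.inf.pi_pt[None],
    }


def method1_metrics(level: Level) -> dict[str, float]:
    """ADH, PDH, DA, ASPO, PSPO for one level."""
    m = metrics_from_arrays(_level_arrays(level))
    return {k: float(m[k][0]) for k in ("adh", "pdh", "da", "aspo", "pspo")}


def method2_metrics(level: Level) -> dict[str, float]:
    """VDH, DDH, MPA, CSPO for one level."""
    m = metrics_from_arrays(_level_arrays(level))
    return {k: float(m[k][0]) for k in ("vdh", "ddh", "mpa", "cspo")}


def composite_metrics(level: Level) -> dict[str, float]:
    """Average disc height, shoelace disc area (EPW² units), EPWR, H/W ratio."""
    m = metrics_from_arrays(_level_arrays(level))
    out = {k: float(m[k][0]) for k in ("avg_dh", "disc_area", "epwr", "hw_ratio")}
    out["self_intersecting"] = bool(m["self_intersecting"][0])
    return out


def level_metrics(level: Level) -> LevelMetrics:
    """All thirteen metrics for one level."""
    m = metrics_from_arrays(_level_arrays(level))
    vals = {k: float(m[k][0]) for k in METRIC_COLUMNS}
    return LevelMetrics(**vals, self_intersecting=bool(m["self_intersecting"][0]))


def metrics_table(subjects: list[Subject]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-level metrics for a subject collection.

    Returns (metrics, skips): one metrics row per computable level with
    subject_id, level_name, the thirteen metric columns, self_intersecting and
    osteo_flag; and one skips row per level that failed with the reason.
    Missing levels are never fabricated.
    """
    # batch all levels through the vectorized core
    rows, corner_stack = [], {k: [] for k in CORNER_KEYS}
    skips = []
    for s in subjects:
        for lv in s.levels:
            try:
                # cheap degeneracy screen so one bad level cannot poison the batch
                endplate_width(lv.inf, "superior")
                endplate_width(lv.sup, "inferior")
            except DegenerateGeometryError as e:
                skips.append({"subject_id": s.subject_id,
                              "level_name": lv.level_name, "reason": str(e)})
                continue
            rows.append((s.subject_id, lv.level_name, bool(lv.osteo_flag)))
            arrs = _level_arrays(lv)
            for k in CORNER_KEYS:
                corner_stack[k].append(arrs[k][0])

    skips_df = pd.DataFrame(skips, columns=["subject_id", "level_name", "reason"])
    if not rows:
        cols = ["subject_id", "level_name", *METRIC_COLUMNS,
                "self_intersecting", "osteo_flag"]
        return pd.DataFrame(columns=cols), skips_df

    c = {k: np.asarray(v) for k, v in corner_stack.items()}
    m = metrics_from_arrays(c)
    out = pd.DataFrame({
        "subject_id": [r[0] for r in rows],
        "level_name": [r[1] for r in rows],
        **{k: m[k] for k in METRIC_COLUMNS},
        "self_intersecting": m["self_intersecting"],
        "osteo_flag": [r[2] for r in rows],
    })
    return out, skips_df
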