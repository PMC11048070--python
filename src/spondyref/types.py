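"""Core domain types for lumbar landmark morphometrics.

Coordinate convention throughout the package: +x is anterior, +y is cephalad
(readers of image-space files with y growing downward can flip on input).
Lengths are in arbitrary units; every reported metric is a ratio, a
percentage of endplate width, or an angle, so no physical scale is required.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VERTEBRAE: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5", "S1")
LEVEL_NAMES: tuple[str, ...] = ("L1L2", "L2L3", "L3L4", "L4L5", "L5S1")

#: level name -> (superior vertebra, inferior vertebra)
LEVEL_PAIRS: dict[str, tuple[str, str]] = {
    "L1L2": ("L1", "L2"),
    "L2L3": ("L2", "L3"),
    "L3L4": ("L3", "L4"),
    "L4L5": ("L4", "L5"),
    "L5S1": ("L5", "S1"),
}

#: the thirteen per-level metric columns, in canonical output order
METRIC_COLUMNS: tuple[str, ...] = (
    "adh", "pdh", "avg_dh", "da", "aspo", "pspo",
    "vdh", "ddh", "mpa", "cspo",
    "disc_area", "epwr", "hw_ratio",
)

#: metrics gating the second trimming pass
GATING_METRICS: tuple[str, ...] = (
    "da", "aspo", "pspo", "avg_dh", "disc_area", "epwr", "hw_ratio",
)


class DegenerateGeometryError(ValueError):
    """Raised when landmark geometry collapses (zero-width endplate, etc.)."""


@dataclass(frozen=True)
class VertebraLandmarks:
    """Four named corners of one vertebral body in the sagittal plane.

    Corners: antero-superior (as_pt), postero-superior (ps_pt),
    antero-inferior (ai_pt), postero-inferior (pi_pt).
    """

    label: str
    as_pt: np.ndarray
    ps_pt: np.ndarray
    ai_pt: np.ndarray
    pi_pt: np.ndarray

    def __post_init__(self):
        for name in ("as_pt", "ps_pt", "ai_pt", "pi_pt"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def violations(self) -> list[str]:
        """Corner-order sanity checks, valid for upright (image-frame) input.

        The checks use raw axes, so they are meaningful only at ingest, before
        any rigid motion is applied; geometry code itself is frame-free.
        """
        out = []
        pts = self.corners
        if not np.all(np.isfinite(pts)):
            out.append(f"{self.label}: non-finite coordinates")
            return out
        if not self.as_pt[0] > self.ps_pt[0]:
            out.append(f"{self.label}: as_pt.x <= ps_pt.x (anterior superior corner not anterior)")
        if not self.ai_pt[0] > self.pi_pt[0]:
            out.append(f"{self.label}: ai_pt.x <= pi_pt.x (anterior inferior corner not anterior)")
        if not self.as_pt[1] > self.ai_pt[1]:
            out.append(f"{self.label}: as_pt.y <= ai_pt.y (superior corner not above inferior)")
        if not self.ps_pt[1] > self.pi_pt[1]:
            out.append(f"{self.label}: ps_pt.y <= pi_pt.y (superior corner not above inferior)")
        return out

    @property
    def corners(self) -> np.ndarray:
        """(4, 2) array in order as, ps, ai, pi."""
        return np.stack([self.as_pt, self.ps_pt, self.ai_pt, self.pi_pt])

    @property
    def centroid(self) -> np.ndarray:
        return self.corners.mean(axis=0)

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0),
                    scale: float = 1.0) -> "VertebraLandmarks":
        """Similarity-transformed copy (rotate about origin, scale, translate)."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.asarray(translation, dtype=float)
        pts = (self.corners @ rot.T) * scale + t
        return VertebraLandmarks(self.label, *pts)


@dataclass
class Level:
    """One intervertebral level: superior and inferior vertebra plus the
    radiologist/CNN-supplied osteophyte-or-sclerosis flag (an input, never
    computed here)."""

    level_name: str
    sup: VertebraLandmarks
    inf: VertebraLandmarks
    osteo_flag: bool = False

    def __post_init__(self):
        pair = LEVEL_PAIRS.get(self.level_name)
        if pair is None:
            raise ValueError(f"unknown level name {self.level_name!r}")
        if (self.sup.label, self.inf.label) != pair:
            raise ValueError(
                f"level {self.level_name}: vertebrae {self.sup.label}/{self.inf.label} "
                f"are not the adjacent pair {pair}")


@dataclass
class Subject:
    """One examined participant: demographics plus up to five levels."""

    subject_id: str
    age: float = float("nan")
    sex: str = ""
    bmi: float = float("nan")
    back_pain: bool | None = None
    position: str = "side-lying"
    levels: list[Level] = field(default_factory=list)

    def __post_init__(self):
        names = [lv.level_name for lv in self.levels]
        if len(names) != len(set(names)):
            raise ValueError(f"subject {self.subject_id}: duplicate level names {names}")
        if not (np.isnan(self.age) or self.age >= 0):
            raise ValueError(f"subject {self.subject_id}: negative age {self.age}")
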