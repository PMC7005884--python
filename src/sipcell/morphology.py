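"""Cell-shape biovolume models and biovolume -> carbon -> nitrogen quotas.

Rod-shaped cells are modeled as capsules (a cylinder capped by two half
spheres), coccoid/archaeal cells as prolate spheroids. Cellular carbon
follows a power-law allometry C = a * V**b; nitrogen follows from a fixed
biomass C:N ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import FG_N_PER_FMOL

__all__ = [
    "CellShape",
    "CellQuota",
    "AllometryParams",
    "DEFAULT_ALLOMETRY",
    "REDFIELD_CN",
    "biovolume",
    "area_to_volume",
    "carbon_content",
    "nitrogen_content",
    "quota_from_shape",
    "quota_from_volume",
]

#: Canonical marine biomass C:N (106:16).
REDFIELD_CN: float = 6.625

_SHAPES = ("capsule", "prolate_spheroid")


@dataclass(frozen=True)
class CellShape:
    """Cell geometry: shape class plus length and width in µm."""

    shape: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.length < self.width:
            raise ValueError("length must be >= width")


@dataclass(frozen=True)
class CellQuota:
    """Biovolume and elemental quotas for one cell or a population mean."""

    volume_um3: float
    carbon_fg: float
    nitrogen_fg: float
    nitrogen_fmol: float


@dataclass(frozen=True)
class AllometryParams:
    """Power-law carbon allometry C[fg] = a * (V[µm³])**b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if not 0 < self.b <= 1:
            raise ValueError("exponent b must be in (0, 1]")


def _solve_allometry(v1: float, c1: float, v2: float, c2: float) -> AllometryParams:
    """Solve a, b exactly from two (volume, carbon) calibration points."""
    b = math.log(c2 / c1) / math.log(v2 / v1)
    a = c1 / v1**b
    return AllometryParams(a=a, b=b)


# Calibrated so 0.06 µm³ -> 50 fg-C and 0.25 µm³ -> 100 fg-C
# (a ≈ 196 fg at V = 1 µm³, b ≈ 0.486).
DEFAULT_ALLOMETRY = _solve_allometry(0.06, 50.0, 0.25, 100.0)


def biovolume(shape: CellShape) -> float:
    """Cell volume (µm³) from the geometric shape model.

    Capsule: pi (w/2)² (l - w) + 4/3 pi (w/2)³; a capsule with l = w
    degenerates to a sphere. Prolate spheroid: (pi/6) l w².
    """
    l, w = shape.length, shape.width
    r = w / 2.0
    if shape.shape == "capsule":
        return math.pi * r * r * (l - w) + (4.0 / 3.0) * math.pi * r**3
    return (math.pi / 6.0) * l * w * w


def area_to_volume(roi_area: float, shape: str, aspect_ratio: float) -> float:
    """Invert a mid-plane projected ROI area to a biovolume (µm³).

    The ROI is treated as the shape's projection: a capsule projects to a
    rectangle w x (l - w) plus a circle of diameter w; a prolate spheroid
    projects to an ellipse of area (pi/4) l w. Given the aspect ratio
    r = l/w, the projection is solved for (l, w) and the volume model
    applied.
    """
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    r = aspect_ratio
    if shape == "prolate_spheroid":
        # area = (pi/4) * r * w^2
        w = math.sqrt(4.0 * roi_area / (math.pi * r))
    elif shape == "capsule":
        # area = w^2 (r - 1) + (pi/4) w^2
        w = math.sqrt(roi_area / (r - 1.0 + math.pi / 4.0))
    else:
        raise ValueError(f"shape must be one of {_SHAPES}, got {shape!r}")
    return biovolume(CellShape(shape=shape, length=r * w, width=w))


def carbon_content(volume_um3: float, params: AllometryParams = DEFAULT_ALLOMETRY) -> float:
    """Cellular carbon (fg-C) from biovolume via the power-law allometry."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return params.a * volume_um3**params.b


def nitrogen_content(carbon_fg: float, cn_ratio: float = REDFIELD_CN) -> tuple[float, float]:
    """Cellular nitrogen as (fg-N, fmol-N) from carbon and a C:N ratio."""
    if cn_ratio <= 0:
        raise ValueError("cn_ratio must be positive")
    if carbon_fg < 0:
        raise ValueError("carbon must be non-negative")
    fg_n = carbon_fg / cn_ratio
    return fg_n, fg_n / FG_N_PER_FMOL


def quota_from_volume(
    volume_um3: float,
    params: AllometryParams = DEFAULT_ALLOMETRY,
    cn_ratio: float = REDFIELD_CN,
) -> CellQuota:
    """Full quota (volume, fg-C, fg-N, fmol-N) from a biovolume."""
    c = carbon_content(volume_um3, params)
    fg_n, fmol_n = nitrogen_content(c, cn_ratio)
    return CellQuota(volume_um3=volume_um3, carbon_fg=c, nitrogen_fg=fg_n, nitrogen_fmol=fmol_n)


def quota_from_shape(
    shape: CellShape,
    params: AllometryParams = DEFAULT_ALLOMETRY,
    cn_ratio: float = REDFIELD_CN,
) -> CellQuota:
    """Full quota from a geometric cell shape."""
    return quota_from_volume(biovolume(shape), params, cn_ratio)
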