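"""Per-cell morphological feature panel from a height map and its mask.

Sixteen features per cell: bulk quantities integrated over the mask
(projected area, volume, dry mass), the 3D surface area of the height
landscape, height-distribution moments (variance, skewness, non-excess
kurtosis), mask shape descriptors (circularity, eccentricity, perimeter,
perimeter/area, convex-hull complexity score, sphericity) and the derived
ratios (SA/V, SA/dry-mass, projected-area/V).  Dry mass follows the
standard phase-microscopy relation: integrated optical path difference
divided by the specific refractive increment alpha (~0.19 um^3/pg for
protein), with OPD = height * delta_n under the uniform-index model, so
dry_mass = volume * delta_n / alpha holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage

from .phase import DEFAULT_DELTA_N, DEFAULT_PASS_FACTOR, DEFAULT_WAVELENGTH_UM, HeightMap
from .segmentation import CellMask

__all__ = [
    "CalibrationParams",
    "CellFeatures",
    "FEATURE_NAMES",
    "compute_bulk_features",
    "compute_surface_area",
    "compute_height_stats",
    "compute_shape_features",
    "extract_all",
]

#: canonical feature order for tables and CSV output
FEATURE_NAMES = (
    "circularity",
    "volume",
    "projected_area",
    "dry_mass",
    "surface_area",
    "sa_to_volume",
    "sa_to_dry_mass",
    "projected_area_to_volume",
    "sphericity",
    "height_variance",
    "height_kurtosis",
    "height_skewness",
    "eccentricity",
    "perimeter",
    "perimeter_to_area",
    "complexity_score",
)

#: units per feature (for table headers)
FEATURE_UNITS = {
    "circularity": "", "volume": "um^3", "projected_area": "um^2",
    "dry_mass": "pg", "surface_area": "um^2", "sa_to_volume": "1/um",
    "sa_to_dry_mass": "um^2/pg", "projected_area_to_volume": "1/um",
    "sphericity": "", "height_variance": "um^2", "height_kurtosis": "",
    "height_skewness": "", "eccentricity": "", "perimeter": "um",
    "perimeter_to_area": "1/um", "complexity_score": "",
}


@dataclass
class CalibrationParams:
    """Physical calibration shared by all feature computations."""

    pixel_size_um: float = 0.5
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    alpha_ri_increment: float = 0.19  # specific refractive increment, um^3/pg
    delta_n: float = DEFAULT_DELTA_N
    pass_factor: int = DEFAULT_PASS_FACTOR

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "wavelength_um", "alpha_ri_increment", "delta_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.15 <= self.alpha_ri_increment <= 0.25:
            warnings.warn(
                f"alpha_ri_increment={self.alpha_ri_increment} outside the usual "
                "0.15-0.25 um^3/pg band"
            )


@dataclass
class CellFeatures:
    """The 16-feature morphology record for one cell at one timepoint."""

    circularity: float = 0.0
    volume: float = 0.0
    projected_area: float = 0.0
    dry_mass: float = 0.0
    surface_area: float = 0.0
    sa_to_volume: float = 0.0
    sa_to_dry_mass: float = 0.0
    projected_area_to_volume: float = 0.0
    sphericity: float = 0.0
    height_variance: float = 0.0
    height_kurtosis: float = float("nan")
    height_skewness: float = float("nan")
    eccentricity: float = 0.0
    perimeter: float = 0.0
    perimeter_to_area: float = 0.0
    complexity_score: float = 0.0
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _as_height_and_mask(hm, mask) -> tuple[np.ndarray, np.ndarray, float]:
    h = hm.height_um if isinstance(hm, HeightMap) else np.asarray(hm, dtype=float)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if h.shape != m.shape:
        raise ValueError("height map and mask must be congruent")
    return h, m, (hm.pixel_size_um if isinstance(hm, HeightMap) else float("nan"))


def compute_bulk_features(
    hm, mask, calib: CalibrationParams
) -> tuple[float, float, float]:
    """Projected area (um^2), volume (um^3) and dry mass (pg) over the mask.

    projected_area = N_px * p^2; volume = sum(h) * p^2;
    dry_mass = sum(h * delta_n) * p^2 / alpha.
    """
    h, m, _ = _as_height_and_mask(hm, mask)
    px2 = calib.pixel_size_um**2
    n = int(np.count_nonzero(m))
    if n == 0:
        warnings.warn("compute_bulk_features: empty mask")
        return 0.0, 0.0, 0.0
    projected_area = n * px2
    volume = float(h[m].sum()) * px2
    dry_mass = volume * calib.delta_n / calib.alpha_ri_increment
    return projected_area, volume, dry_mass


def compute_surface_area(hm, mask, calib: CalibrationParams) -> float:
    """3D area (um^2) of the height surface over the mask.

    Each masked pixel quad is split into two triangles on its four corner
    heights, where a corner height is the mean of the adjacent masked
    pixel-center heights.  Boundary quads are mask-clipped: the one-pixel
    dilation ring around the mask contributes only its excess area over a
    flat quad, which captures the descent of the surface to the background
    at the cell edge without adding any area for flat surroundings.  A flat
    field gives exactly the projected area; any relief strictly increases
    the result.
    """
    h, m, _ = _as_height_and_mask(hm, mask)
    if not m.any():
        return 0.0
    p = calib.pixel_size_um
    H, W = h.shape
    hmask = np.where(m, h, 0.0)
    # corner grids (H+1, W+1): sums and counts of adjacent masked pixels
    hsum = np.zeros((H + 1, W + 1))
    cnt = np.zeros((H + 1, W + 1))
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        hsum[dr : dr + H, dc : dc + W] += hmask
        cnt[dr : dr + H, dc : dc + W] += m
    corner = np.divide(hsum, cnt, out=np.zeros_like(hsum), where=cnt > 0)

    def quad_areas(sel: np.ndarray) -> np.ndarray:
        c00 = corner[:-1, :-1][sel]
        c01 = corner[:-1, 1:][sel]
        c10 = corner[1:, :-1][sel]
        c11 = corner[1:, 1:][sel]
        # triangles (c00, c10, c01) and (c11, c01, c10) on a p x p quad
        a1 = 0.5 * p * np.sqrt((c10 - c00) ** 2 + (c01 - c00) ** 2 + p**2)
        a2 = 0.5 * p * np.sqrt((c01 - c11) ** 2 + (c10 - c11) ** 2 + p**2)
        return a1 + a2

    core = float(quad_areas(m).sum())
    ring = ndimage.binary_dilation(m, structure=np.ones((3, 3), bool)) & ~m
    skirt = float(np.maximum(quad_areas(ring) - p**2, 0.0).sum())
    return core + skirt


def compute_height_stats(hm, mask) -> tuple[float, float, float]:
    """Population variance (um^2), skewness and non-excess kurtosis of heights.

    Kurtosis uses the non-excess convention (normal distribution -> 3).
    Constant heights give variance 0 with skewness/kurtosis NaN.
    """
    h, m, _ = _as_height_and_mask(hm, mask)
    vals = h[m]
    if vals.size < 4:
        raise ValueError("compute_height_stats requires >= 4 mask pixels")
    mu = vals.mean()
    var = float(np.mean((vals - mu) ** 2))
    if var == 0.0:
        return 0.0, float("nan"), float("nan")
    z = vals - mu
    skew = float(np.mean(z**3) / var**1.5)
    kurt = float(np.mean(z**4) / var**2)
    return var, skew, kurt


def _trace_boundary_chain(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbour boundary trace (clockwise) of a single 8-connected
    component; returns a closed pixel chain (last element == first).  A
    1-pixel mask returns a single-element chain."""
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        return []
    if pts.shape[0] == 1:
        return [tuple(pts[0])]
    m = np.pad(mask, 1)
    start = tuple(np.argwhere(m)[0])
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    chain = [start]
    cur = start
    back = (start[0], start[1] - 1)  # west of start: background by scan order
    first_transition = None
    while True:
        bi = nbrs.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = nbrs[(bi + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if m[cand]:
                nxt = cand
                pd = nbrs[(bi + k - 1) % 8]
                back = (cur[0] + pd[0], cur[1] + pd[1])
                break
        if nxt is None:  # isolated pixel (cannot happen for size >= 2, safety)
            break
        transition = (cur, nxt)
        if first_transition is None:
            first_transition = transition
        elif transition == first_transition:
            break
        chain.append(nxt)
        cur = nxt
    return [(r - 1, c - 1) for r, c in chain]


#: corner-corrected chain-step weights (Kulpa): calibrated so that digital
#: circles measure within ~1% of their true circumference
_W_AXIAL = 0.948
_W_DIAGONAL = 1.343


def _chain_perimeter_px(chain: list[tuple[int, int]]) -> float:
    if len(chain) <= 1:
        return 4.0 * _W_AXIAL  # outline of a single pixel
    d = np.abs(np.diff(np.asarray(chain, dtype=int), axis=0))
    diagonal = int(np.sum(d.max(axis=1) > 0) - np.sum(d.sum(axis=1) == 1))
    axial = int(d.shape[0] - diagonal)
    return _W_AXIAL * axial + _W_DIAGONAL * diagonal


def _eccentricity(mask: np.ndarray) -> float:
    """sqrt(1 - (minor/major)^2) of the second-central-moment ellipse."""
    ys, xs = np.nonzero(mask)
    if ys.size < 2:
        return 0.0
    cy, cx = ys.mean(), xs.mean()
    mu20 = np.mean((xs - cx) ** 2)
    mu02 = np.mean((ys - cy) ** 2)
    mu11 = np.mean((xs - cx) * (ys - cy))
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    major = (mu20 + mu02) / 2.0 + common
    minor = (mu20 + mu02) / 2.0 - common
    if major <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - minor / major)))


def _hull_area_px(mask: np.ndarray) -> float:
    """Convex-hull area (px^2) over boundary pixel centers; 0 if degenerate."""
    boundary = mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    pts = np.argwhere(boundary).astype(float)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D "volume" is the area
    except QhullError:  # collinear points
        return 0.0


def compute_shape_features(
    mask,
    calib: CalibrationParams,
    volume: Optional[float] = None,
    surface_area: Optional[float] = None,
    perimeter_estimator: str = "chain",
) -> tuple[float, float, float, float, float, float]:
    """Mask shape descriptors.

    Returns (circularity, eccentricity, perimeter_um, perimeter_to_area,
    complexity_score, sphericity).  Perimeter uses the 8-connected boundary
    chain with corner-corrected step weights (0.948 axial, 1.343 diagonal
    per pixel), which keeps digital circles within ~1% of their true
    circumference (``perimeter_estimator="crofton"`` switches to the
    Crofton estimator).
    Circularity = min(1, 4*pi*A/P^2); complexity = (hull - area)/hull with
    the hull taken over boundary pixel centers; sphericity =
    pi^(1/3) * (6V)^(2/3) / SA (dimensionless), NaN unless volume and
    surface area are supplied.
    """
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    n_px = int(np.count_nonzero(m))
    if n_px == 0:
        raise ValueError("compute_shape_features: empty mask")
    p = calib.pixel_size_um
    area = n_px * p**2

    if perimeter_estimator == "chain":
        perim = _chain_perimeter_px(_trace_boundary_chain(m)) * p
    elif perimeter_estimator == "crofton":
        from skimage.measure import perimeter_crofton

        perim = float(perimeter_crofton(m, directions=4)) * p
    else:
        raise ValueError("perimeter_estimator must be 'chain' or 'crofton'")

    circularity = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    ecc = _eccentricity(m)
    hull_px = _hull_area_px(m)
    complexity = max(0.0, (hull_px - n_px) / hull_px) if hull_px > 0 else 0.0
    perim_to_area = perim / area
    if volume is not None and surface_area is not None and surface_area > 0:
        sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area)
    else:
        sphericity = float("nan")
    return circularity, ecc, perim, perim_to_area, complexity, sphericity


def extract_all(hm, mask, calib: CalibrationParams) -> CellFeatures:
    """Assemble the full 16-feature record; ratios recomputed from components."""
    h, m, _ = _as_height_and_mask(hm, mask)
    if not m.any():
        warnings.warn("extract_all: empty mask, returning flagged zero record")
        return CellFeatures(flags=("empty_mask",))

    projected_area, volume, dry_mass = compute_bulk_features(hm, mask, calib)
    surface_area = compute_surface_area(hm, mask, calib)
    flags: list[str] = []
    try:
        variance, skew, kurt = compute_height_stats(hm, mask)
    except ValueError:
        variance, skew, kurt = 0.0, float("nan"), float("nan")
        flags.append("too_few_pixels_for_moments")
    circ, ecc, perim, perim_to_area, complexity, sphericity = compute_shape_features(
        mask, calib, volume=volume, surface_area=surface_area
    )
    if np.isnan(skew) or np.isnan(kurt):
        flags.append("degenerate_height_moments")

    return CellFeatures(
        circularity=circ,
        volume=volume,
        projected_area=projected_area,
        dry_mass=dry_mass,
        surface_area=surface_area,
        sa_to_volume=surface_area / volume if volume > 0 else float("nan"),
        sa_to_dry_mass=surface_area / dry_mass if dry_mass > 0 else float("nan"),
        projected_area_to_volume=projected_area / volume if volume > 0 else float("nan"),
        sphericity=sphericity,
        height_variance=variance,
        height_kurtosis=kurt,
        height_skewness=skew,
        eccentricity=ecc,
        perimeter=perim,
        perimeter_to_area=perim_to_area,
        complexity_score=complexity,
        flags=tuple(flags),
    )
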