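"""SUV metrics and 3D gray-level co-occurrence (Haralick) texture features.

Pipeline per region of interest (the pelvic MTV):

1. SUVmax / SUVmean over the region, SUVpeak as the mean SUV in a 1 cm^3
   sphere of voxel centers around the hottest voxel (radius 6.2 mm in world
   millimeters, clipped to the image bounds).
2. Gray-level discretization, either to a fixed number of levels (default
   Ng = 25) or to a fixed bin width in SUV.
3. One co-occurrence matrix per 3D direction (the 13 unique Chebyshev-
   distance-1 offsets), accumulated symmetrically over all in-region voxel
   pairs and normalized to sum 1.
4. Sixteen scalar texture features per matrix; the reported value of each
   feature is the unweighted mean over the non-empty directions (matrix
   merging before feature computation available as a config alternative).

Entropy-family features use the natural logarithm by default (base-2
switchable); 0*log(0) is taken as 0 throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, SUVVolume

TEXTURE_FEATURES = [
    "entropy",
    "homogeneity",
    "contrast",
    "correlation",
    "angular_second_moment",
    "difference_entropy",
    "difference_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "cluster_prominence",
    "cluster_shade",
    "maximum_probability",
    "imc1",
    "imc2",
]

SUV_FEATURES = ["suv_max", "suv_mean", "suv_peak"]
ALL_FEATURES = SUV_FEATURES + TEXTURE_FEATURES

#: the 13 unique distance-1 (Chebyshev) 3D directions (one per +-pair)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: radius of a 1 cm^3 sphere, for SUVpeak
PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


class EmptyCooccurrenceError(ValueError):
    """No voxel pair exists for the requested offset."""


@dataclass(frozen=True)
class RadiomicsConfig:
    mode: str = "fixed-bin-number"   # or "fixed-bin-width"
    n_levels: int = 25
    bin_width: float = 25.0          # SUV, used in fixed-bin-width mode
    log_base: str = "natural"        # or "base2"
    merge_directions: bool = False

    def __post_init__(self):
        if self.mode not in ("fixed-bin-number", "fixed-bin-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.log_base not in ("natural", "base2"):
            raise ValueError(f"unknown log base {self.log_base!r}")


@dataclass
class DiscretizedVolume:
    """Gray levels 1..Ng inside the region, exactly 0 outside."""

    levels: np.ndarray
    n_levels: int
    mode: str
    bin_param: float


@dataclass
class GLCM:
    """Symmetric, normalized co-occurrence matrix P(i, j), i, j = 1..Ng."""

    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(P < 0):
            raise ValueError("GLCM entries must be >= 0")
        if abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM must sum to 1")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        self.P = P

    @property
    def n_levels(self) -> int:
        return self.P.shape[0]


# ---------------------------------------------------------------------------
# SUV metrics
# ---------------------------------------------------------------------------


def _peak_sphere_offsets(spacing_mm) -> np.ndarray:
    """Integer voxel offsets whose centers fall within the 1 cm^3 sphere."""
    reach = [int(np.floor(PEAK_RADIUS_MM / s)) for s in spacing_mm]
    offs = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d2 = (dx * spacing_mm[0]) ** 2 + (dy * spacing_mm[1]) ** 2 + (dz * spacing_mm[2]) ** 2
                if d2 <= PEAK_RADIUS_MM ** 2:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def suv_metrics(volume: SUVVolume, mtv: BinaryMask) -> tuple[float, float, float]:
    """(SUVmax, SUVmean, SUVpeak) over the MTV.

    SUVpeak averages the SUV of all voxels (not restricted to the MTV) whose
    centers lie within a 1 cm^3 sphere around the hottest MTV voxel, clipped
    to the image bounds.
    """
    region = mtv.values.astype(bool)
    if not region.any():
        raise ValueError("empty MTV")
    vals = volume.values
    suv_max = float(vals[region].max())
    suv_mean = float(vals[region].mean())
    # hottest MTV voxel (first in C order among ties)
    masked = np.where(region, vals, -np.inf)
    center = np.unravel_index(int(np.argmax(masked)), vals.shape)
    offs = _peak_sphere_offsets(volume.spacing_mm)
    coords = np.asarray(center) + offs
    inb = np.all((coords >= 0) & (coords < np.asarray(vals.shape)), axis=1)
    coords = coords[inb]
    suv_peak = float(vals[coords[:, 0], coords[:, 1], coords[:, 2]].mean())
    return suv_max, suv_mean, suv_peak


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize(
    volume: SUVVolume, mtv: BinaryMask, mode: str = "fixed-bin-number",
    bin_param: float = 25,
) -> DiscretizedVolume:
    """Map in-region SUVs to integer gray levels 1..Ng."""
    if bin_param <= 0:
        raise ValueError("bin_param must be > 0")
    region = mtv.values.astype(bool)
    if not region.any():
        raise ValueError("empty MTV")
    vals = volume.values[region].astype(float)
    levels = np.zeros(volume.values.shape, dtype=np.int32)
    lo, hi = float(vals.min()), float(vals.max())
    if mode == "fixed-bin-number":
        ng = int(bin_param)
        if hi == lo:
            lv = np.ones(vals.shape, dtype=np.int32)
        else:
            lv = np.floor(ng * (vals - lo) / (hi - lo)).astype(np.int32) + 1
            np.clip(lv, 1, ng, out=lv)
        n_levels = ng
    elif mode == "fixed-bin-width":
        lv = np.floor((vals - lo) / float(bin_param)).astype(np.int32) + 1
        n_levels = int(lv.max())
    else:
        raise ValueError(f"unknown discretization mode {mode!r}")
    levels[region] = lv
    return DiscretizedVolume(levels, n_levels, mode, float(bin_param))


# ---------------------------------------------------------------------------
# Co-occurrence accumulation
# ---------------------------------------------------------------------------


def _offset_slices(shape, offset):
    sa, sb = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return tuple(sa), tuple(sb)


def build_glcm(d: DiscretizedVolume, offset: tuple[int, int, int]) -> GLCM:
    """Symmetric normalized GLCM for one 3D offset (Chebyshev distance 1)."""
    if all(o == 0 for o in offset):
        raise ValueError("offset must be non-zero")
    if max(abs(o) for o in offset) != 1:
        raise ValueError("offset must have Chebyshev norm 1")
    ng = d.n_levels
    sa, sb = _offset_slices(d.levels.shape, offset)
    A, B = d.levels[sa], d.levels[sb]
    valid = (A > 0) & (B > 0)
    if not valid.any():
        raise EmptyCooccurrenceError(f"no voxel pair for offset {offset}")
    a, b = A[valid] - 1, B[valid] - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    sym = counts + counts.T
    return GLCM(sym / sym.sum())


# ---------------------------------------------------------------------------
# Haralick features
# ---------------------------------------------------------------------------


def _xlogx(p: np.ndarray, log) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * log(p[nz])
    return out


def haralick_features(g: GLCM, log_base: str = "natural") -> dict[str, float]:
    """The 16 co-occurrence texture features of one GLCM."""
    log = np.log if log_base == "natural" else np.log2
    P = g.P
    ng = g.n_levels
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal / cross-diagonal sums
    ks = np.arange(2, 2 * ng + 1)           # i + j
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, (I + J).ravel(), P.ravel())
    p_sum = p_sum[2:]
    kd = np.arange(0, ng)                   # |i - j|
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())

    asm = float((P ** 2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if sigma_x * sigma_y == 0:
        correlation = 1.0  # single gray level: perfectly predictable
    else:
        correlation = float(((I * J * P).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    entropy = float(-_xlogx(P, log).sum())
    homogeneity = float((P / (1.0 + np.abs(I - J))).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())
    sum_average = float((ks * p_sum).sum())
    sum_entropy = float(-_xlogx(p_sum, log).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    difference_entropy = float(-_xlogx(p_diff, log).sum())
    mu_diff = float((kd * p_diff).sum())
    difference_variance = float(((kd - mu_diff) ** 2 * p_diff).sum())
    dev = I + J - mu_x - mu_y
    cluster_shade = float((dev ** 3 * P).sum())
    cluster_prominence = float((dev ** 4 * P).sum())
    max_prob = float(P.max())

    # informational measures of correlation
    hx = float(-_xlogx(px, log).sum())
    hy = float(-_xlogx(py, log).sum())
    pxpy = np.outer(px, py)
    lg = np.zeros_like(pxpy)
    nz = pxpy > 0
    lg[nz] = log(pxpy[nz])
    hxy1 = float(-(P * lg).sum())
    hxy2 = float(-_xlogx(pxpy, log).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "entropy": entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
        "angular_second_moment": asm,
        "difference_entropy": difference_entropy,
        "difference_variance": difference_variance,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "maximum_probability": max_prob,
        "imc1": imc1,
        "imc2": imc2,
    }


# ---------------------------------------------------------------------------
# Per-patient feature extraction
# ---------------------------------------------------------------------------


def extract_features(
    volume: SUVVolume, mtv: BinaryMask, config: RadiomicsConfig = RadiomicsConfig()
) -> dict[str, float]:
    """SUV metrics plus direction-averaged texture features (19 values)."""
    region = mtv.values.astype(bool)
    if region.sum() < 2:
        raise ValueError("MTV too small for texture (need >= 2 voxels)")
    suv_max, suv_mean, suv_peak = suv_metrics(volume, mtv)
    bin_param = config.n_levels if config.mode == "fixed-bin-number" else config.bin_width
    d = discretize(volume, mtv, config.mode, bin_param)

    if config.merge_directions:
        ng = d.n_levels
        total = np.zeros((ng, ng))
        any_pair = False
        for off in OFFSETS_3D:
            try:
                g = build_glcm(d, off)
            except EmptyCooccurrenceError:
                continue
            # recover un-normalized symmetric counts are not kept; accumulate
            # probability mass weighted equally per direction
            total += g.P
            any_pair = True
        if not any_pair:
            raise ValueError("MTV too small for texture (no co-occurring pair)")
        texture = haralick_features(GLCM(total / total.sum()), config.log_base)
    else:
        per_dir: list[dict[str, float]] = []
        for off in OFFSETS_3D:
            try:
                g = build_glcm(d, off)
            except EmptyCooccurrenceError:
                continue
            per_dir.append(haralick_features(g, config.log_base))
        if not per_dir:
            raise ValueError("MTV too small for texture (no co-occurring pair)")
        texture = {
            name: float(np.mean([f[name] for f in per_dir])) for name in TEXTURE_FEATURES
        }

    out = {"suv_max": suv_max, "suv_mean": suv_mean, "suv_peak": suv_peak}
    out.update({name: texture[name] for name in TEXTURE_FEATURES})
    return out
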