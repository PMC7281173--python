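"""Synthetic pelvic-PET phantom and cohort generator.

Emulates the data a pelvic bone-marrow radiomics analysis consumes: per
patient a 3D SUV volume with the reference voxel grid (5.5 x 5.5 x 3.3 mm),
a pelvic-bone search mask, and a cohort row (scanner batch, biopsy
involvement, REL/ABS, cellularity, WBC, LDH, Ki-67).

The uptake model is a stationary Gaussian random field over the marrow mask:
marrow SUV = baseline + class-dependent mean shift + correlated texture
field, plus Poisson-count focal spherical lesions whose expected count grows
linearly with REL.  The mean (SUV signal) and the spatial correlation length
/ field SD (texture signal) are controlled independently, so cohorts with
texture-only class contrast (equal marrow means) can be generated.  Scanner
batch effects (PSF blur, gain, offset, noise scaling) are applied last.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

from . import io as mio
from .cohort import compute_abs
from .io import BinaryMask, CohortRecord, SUVVolume

# ---------------------------------------------------------------------------
# Truncated-normal distribution spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal parameterized by the *underlying* loc/scale.

    Factories solve for loc/scale so the truncated law has prescribed
    moments (``from_moments``) or a prescribed upper-tail mass
    (``from_tail``).
    """

    loc: float
    scale: float
    low: float = 0.0
    high: float = 100.0

    def _ab(self):
        return (self.low - self.loc) / self.scale, (self.high - self.loc) / self.scale

    @property
    def mean(self) -> float:
        a, b = self._ab()
        return float(stats.truncnorm.mean(a, b, loc=self.loc, scale=self.scale))

    @property
    def sd(self) -> float:
        a, b = self._ab()
        return float(stats.truncnorm.std(a, b, loc=self.loc, scale=self.scale))

    def sf(self, x: float) -> float:
        a, b = self._ab()
        return float(stats.truncnorm.sf(x, a, b, loc=self.loc, scale=self.scale))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng)

    @classmethod
    def from_moments(cls, mean: float, sd: float, low: float = 0.0, high: float = 100.0) -> "TruncatedNormal":
        """Solve for underlying loc/scale so the truncated mean/SD match the
        targets (nearest feasible fit: strongly skewed targets can fall just
        outside the truncated-normal family, in which case the closest
        member is returned)."""

        def resid(p):
            loc, log_scale = p
            scale = np.exp(log_scale)
            a, b = (low - loc) / scale, (high - loc) / scale
            m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
            return [(float(m) - mean) / sd, (float(np.sqrt(v)) - sd) / sd]

        sol = optimize.least_squares(
            resid, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        return cls(float(sol.x[0]), float(np.exp(sol.x[1])), low, high)

    @classmethod
    def from_tail(
        cls, threshold: float, tail_prob: float, scale: float,
        low: float = 0.0, high: float = 100.0,
    ) -> "TruncatedNormal":
        """Solve for loc (given underlying scale) so P(X >= threshold) = tail_prob."""

        def f(loc):
            a, b = (low - loc) / scale, (high - loc) / scale
            return stats.truncnorm.sf(threshold, a, b, loc=loc, scale=scale) - tail_prob

        loc = optimize.brentq(f, low - 5 * scale, high + 5 * scale, xtol=1e-10)
        return cls(float(loc), scale, low, high)


@dataclass(frozen=True)
class BetaPercent:
    """Beta on [0, 100] matched to mean/SD; alternative REL family."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return 100.0 * self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return 100.0 * float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return 100.0 * rng.beta(self.alpha, self.beta, size=n)

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "BetaPercent":
        mu, var = mean / 100.0, (sd / 100.0) ** 2
        if var >= mu * (1 - mu):
            raise ValueError("variance too large for a beta on [0, 100]")
        k = mu * (1 - mu) / var - 1.0
        return cls(mu * k, (1 - mu) * k)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and uptake-model parameters of one synthetic patient volume.

    ``texture_corr_length_mm`` and ``texture_sd`` are (uninvolved, involved)
    pairs; involved marrow additionally gains a mean shift of
    ``mean_shift_per_rel * REL`` SUV and a field-SD inflation of
    ``(1 + heterogeneity_per_rel * REL / 100)``, so both contrast channels
    grow monotonically with the degree of infiltration.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing_mm: tuple[float, float, float] = (5.5, 5.5, 3.3)
    background_suv: float = 0.8
    marrow_suv_mean: float = 2.0
    texture_corr_length_mm: tuple[float, float] = (6.0, 12.0)
    texture_sd: tuple[float, float] = (0.25, 0.30)
    mean_shift_per_rel: float = 0.008      # SUV per % REL
    heterogeneity_per_rel: float = 1.0     # field-SD inflation at REL=100
    lesion_rate_per_rel: float = 0.05      # expected focal lesions per % REL
    lesion_suv_boost: float = 1.5
    lesion_radius_mm: float = 8.0
    noise_sd: float = 0.12

    def __post_init__(self):
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        for name in ("background_suv", "marrow_suv_mean", "lesion_rate_per_rel",
                     "lesion_suv_boost", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.texture_sd) or any(c <= 0 for c in self.texture_corr_length_mm):
            raise ValueError("texture parameters must be non-negative (corr length > 0)")

    @classmethod
    def texture_only(cls) -> "PhantomSpec":
        """Equal-marrow-mean configuration: classes differ only in the
        spatial correlation structure of the uptake field (no mean shift, no
        focal lesions, equal marginal SD).  Both correlation lengths sit
        well above the largest scanner PSF sigma so batch blur attenuates
        the two classes' field amplitude almost equally, keeping the class
        contrast out of the SUV metrics."""
        return cls(
            texture_corr_length_mm=(8.0, 14.0),
            texture_sd=(0.30, 0.30),
            mean_shift_per_rel=0.0,
            heterogeneity_per_rel=0.0,
            lesion_rate_per_rel=0.0,
        )


@dataclass(frozen=True)
class ScannerEffect:
    """Batch effect of one scanner model: PSF blur, gain, offset, noise."""

    scanner_id: str
    psf_fwhm_mm: float
    gain: float
    offset: float
    noise_scale: float

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


def default_scanner_effects() -> dict[str, ScannerEffect]:
    """Four scanner batches with mild effects (blur 4-8 mm FWHM, gain
    0.9-1.1) so the class signal survives harmonizable distortion."""
    return {
        "S1": ScannerEffect("S1", 4.0, 1.00, 0.00, 1.0),
        "S2": ScannerEffect("S2", 5.5, 1.10, 0.05, 0.8),
        "S3": ScannerEffect("S3", 7.0, 0.90, -0.05, 1.2),
        "S4": ScannerEffect("S4", 8.0, 1.05, 0.10, 1.1),
    }


def _default_rel() -> TruncatedNormal:
    return TruncatedNormal.from_moments(33.0, 29.1)


def _default_ki67_involved() -> TruncatedNormal:
    # high (>=30%) fraction among involved ~ 0.493
    return TruncatedNormal.from_tail(30.0, 0.493, 23.7)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level sampling model.

    Class-conditional laboratory distributions are chosen so the pooled
    moments at the default prevalence match the reference cohort (WBC
    10.5 +- 11.9 x10^9/L, LDH 232.3 +- 86.0 U/L, Ki-67 28.9 +- 23.7%) while
    involved patients sit higher, making labs class-informative.
    """

    n_patients: int = 97
    involvement_prevalence: float = 0.691
    rel_distribution: TruncatedNormal | BetaPercent = field(default_factory=_default_rel)
    cellularity_distribution: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(68.0, 15.0)
    )
    wbc_involved: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(12.0, 13.0, 0.5, 150.0)
    )
    wbc_uninvolved: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(7.0, 8.0, 0.5, 150.0)
    )
    ldh_involved: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(242.0, 90.0, 50.0, 1500.0)
    )
    ldh_uninvolved: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(210.0, 70.0, 50.0, 1500.0)
    )
    ki67_involved: TruncatedNormal = field(default_factory=_default_ki67_involved)
    ki67_uninvolved: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal.from_moments(20.0, 18.0)
    )
    scanner_ids: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.involvement_prevalence <= 1.0):
            raise ValueError("involvement_prevalence outside [0, 1]")
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")


# ---------------------------------------------------------------------------
# Volume synthesis
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _pelvis_mask_array(grid_shape, voxel_spacing_mm) -> np.ndarray:
    nx, ny, nz = grid_shape
    if min(grid_shape) < 8:
        raise ValueError(f"degenerate grid {grid_shape}: every axis must have >= 8 voxels")
    sx, sy, sz = voxel_spacing_mm
    fov = (nx * sx, ny * sy, nz * sz)
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    mask = np.zeros(grid_shape, dtype=bool)
    # two mirrored ellipsoid shells standing in for the iliac wings
    a, b, c = 0.18 * fov[0], 0.30 * fov[1], 0.45 * fov[2]
    for fx in (0.28, 0.72):
        cx, cy, cz = fx * fov[0], 0.5 * fov[1], 0.5 * fov[2]
        q = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2)
        mask |= (q >= 0.55) & (q <= 1.0)
    if not mask.any():
        raise ValueError("pelvis mask construction produced an empty mask")
    return mask


def generate_pelvis_mask(spec: PhantomSpec) -> BinaryMask:
    """Deterministic two-winged pelvic search region for the given geometry."""
    arr = _pelvis_mask_array(spec.grid_shape, spec.voxel_spacing_mm)
    return BinaryMask(arr.astype(np.uint8), spec.voxel_spacing_mm)


def _grf(rng: np.random.Generator, shape, corr_length_mm, spacing, sd) -> np.ndarray:
    """Stationary Gaussian random field with unit-marginal SD scaled to sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    smooth_sd = smooth.std()
    if smooth_sd == 0:
        return np.zeros(shape)
    return sd * smooth / smooth_sd


def generate_patient_volume(
    spec: PhantomSpec,
    involved: bool,
    rel_percent: float,
    effect: ScannerEffect,
    seed: int,
) -> SUVVolume:
    """Synthesize one patient's SUV volume; reproducible given ``seed``."""
    if not (0.0 <= rel_percent <= 100.0):
        raise ValueError(f"rel_percent={rel_percent} outside [0, 100]")
    if not involved and rel_percent != 0:
        raise ValueError("uninvolved patient must have rel_percent = 0")
    rng = np.random.default_rng(seed)
    mask = _pelvis_mask_array(spec.grid_shape, spec.voxel_spacing_mm)
    spacing = spec.voxel_spacing_mm

    cls = 1 if involved else 0
    sd_eff = spec.texture_sd[cls] * (1.0 + spec.heterogeneity_per_rel * rel_percent / 100.0)
    fld = _grf(rng, spec.grid_shape, spec.texture_corr_length_mm[cls], spacing, sd_eff)

    vol = np.full(spec.grid_shape, spec.background_suv, dtype=float)
    marrow = spec.marrow_suv_mean + spec.mean_shift_per_rel * rel_percent + fld
    vol[mask] = marrow[mask]

    # focal spherical lesions, expected count linear in REL
    lam = spec.lesion_rate_per_rel * rel_percent
    n_lesions = int(rng.poisson(lam)) if lam > 0 else 0
    if n_lesions > 0:
        idx = np.argwhere(mask)
        centers = idx[rng.integers(0, len(idx), size=n_lesions)]
        grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
        for cvox in centers:
            d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, cvox, spacing))
            sphere = (d2 <= spec.lesion_radius_mm ** 2) & mask
            vol[sphere] += spec.lesion_suv_boost

    # scanner effect: PSF blur, gain, offset, scaled noise
    if effect.psf_fwhm_mm > 0:
        sigma_mm = effect.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        vol = gaussian_filter(vol, sigma=[sigma_mm / s for s in spacing], mode="nearest")
    vol = effect.gain * vol + effect.offset
    noise_sd = spec.noise_sd * effect.noise_scale
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, spec.grid_shape)
    np.clip(vol, 0.0, None, out=vol)
    return SUVVolume(vol.astype(np.float32), spacing)


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------


def generate_cohort_table(cspec: CohortSpec) -> pd.DataFrame:
    """Sample the cohort CSV (no volumes): involvement, REL/cellularity/ABS,
    scanner assignment (uniform over 4), and class-conditional labs."""
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients
    involved = rng.random(n) < cspec.involvement_prevalence
    scanner = np.array(cspec.scanner_ids)[rng.integers(0, len(cspec.scanner_ids), n)]
    rel = np.zeros(n)
    n_inv = int(involved.sum())
    rel[involved] = cspec.rel_distribution.sample(rng, n_inv)
    cellularity = cspec.cellularity_distribution.sample(rng, n)
    abs_inv = cellularity * rel / 100.0

    wbc = np.where(involved, np.nan, np.nan)
    wbc = np.empty(n)
    wbc[involved] = cspec.wbc_involved.sample(rng, n_inv)
    wbc[~involved] = cspec.wbc_uninvolved.sample(rng, n - n_inv)
    ldh = np.empty(n)
    ldh[involved] = cspec.ldh_involved.sample(rng, n_inv)
    ldh[~involved] = cspec.ldh_uninvolved.sample(rng, n - n_inv)
    ki67 = np.empty(n)
    ki67[involved] = cspec.ki67_involved.sample(rng, n_inv)
    ki67[~involved] = cspec.ki67_uninvolved.sample(rng, n - n_inv)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "scanner_id": scanner,
            "involved": involved.astype(int),
            "rel": rel,
            "cellularity": cellularity,
            "abs": abs_inv,
            "wbc": wbc,
            "ldh": ldh,
            "ki67": ki67,
        }
    )


def patient_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-patient child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def simulate_cohort_volumes(
    table: pd.DataFrame,
    pspec: PhantomSpec,
    effects: dict[str, ScannerEffect] | None = None,
    master_seed: int = 0,
):
    """Yield ``(row, SUVVolume, BinaryMask)`` per patient, in table order."""
    effects = effects or default_scanner_effects()
    seeds = patient_seeds(master_seed, len(table))
    mask = generate_pelvis_mask(pspec)
    for i, row in enumerate(table.itertuples(index=False)):
        vol = generate_patient_volume(
            pspec,
            involved=bool(row.involved),
            rel_percent=float(row.rel),
            effect=effects[str(row.scanner_id)],
            seed=int(seeds[i]),
        )
        yield row, vol, mask


def generate_cohort(
    cspec: CohortSpec,
    pspec: PhantomSpec,
    outdir: str | Path,
    effects: dict[str, ScannerEffect] | None = None,
) -> pd.DataFrame:
    """Write one NIfTI volume + mask per patient plus cohort.csv and a JSON
    manifest recording all spec parameters and the master seed."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {outdir}") from exc

    table = generate_cohort_table(cspec)
    records = mio.records_from_frame(table)  # validates invariants
    for rec in records:
        rec.validate()
    mask_path = outdir / "pelvis_mask.nii.gz"
    first = True
    for row, vol, mask in simulate_cohort_volumes(table, pspec, effects, cspec.seed):
        if first:
            mio.write_mask(mask, mask_path)
            first = False
        mio.write_volume(vol, outdir / f"{row.patient_id}_suv.nii.gz")
    table.to_csv(outdir / "cohort.csv", index=False)
    manifest = {
        "master_seed": cspec.seed,
        "n_patients": cspec.n_patients,
        "involvement_prevalence": cspec.involvement_prevalence,
        "phantom_spec": {k: getattr(pspec, k) for k in pspec.__dataclass_fields__},
        "scanner_effects": {
            k: v.__dict__ for k, v in (effects or default_scanner_effects()).items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return table
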