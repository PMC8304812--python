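"""Synthetic phantom nodule cohorts.

Each phantom is a spherical nodule with a radially graded density profile
(dense core fading to a lighter rim, as in solid lung lesions) plus
spatially correlated Gaussian noise, embedded in a lung-like background
set well below the clipping window so mask leaks clamp visibly to CTmin.
Inter-observer delineation variability is emulated by perturbing the base
mask boundary with a smooth random radial displacement field — masks stay
connected and contour-like, unlike independent voxel flips.

Every output is a pure function of (parameters, seed): one master seed
spawns per-nodule child seeds that are recorded in the cohort manifest so
any single nodule can be re-generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import NoduleMask, VoxelVolume, write_image

#: HU value of the background surrounding the nodule; below any plausible
#: clipping floor, so accidentally included voxels clamp to CTmin.
BACKGROUND_HU = -1000.0

#: Correlation length (voxels) of the rater boundary-jitter field.
JITTER_SMOOTHING_VOXELS = 3.0

_MAX_RATER_RETRIES = 10


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of one phantom nodule."""

    grid_shape: tuple[int, int, int] = (28, 28, 28)
    nodule_radius: float = 6.0
    core_hu: float = 0.0
    rim_hu: float = -400.0
    noise_sigma: float = 60.0
    noise_correlation_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodule_radius < 2:
            raise ValueError("nodule_radius must be >= 2 voxels")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(n < 2 * self.nodule_radius + 4 for n in self.grid_shape):
            raise ValueError(
                f"nodule of radius {self.nodule_radius} plus a 2-voxel margin "
                f"does not fit in grid {self.grid_shape}"
            )


@dataclass(frozen=True)
class RaterModel:
    """Stochastic model of inter-observer contouring differences."""

    n_raters: int = 4
    boundary_jitter_sigma: float = 1.0
    dilation_bias: float = 0.0
    min_dice: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")
        if not 0 < self.min_dice <= 1:
            raise ValueError("min_dice must be in (0, 1]")
        if self.boundary_jitter_sigma < 0:
            raise ValueError("boundary_jitter_sigma must be >= 0")


def _correlated_noise(shape, sigma, corr_len, rng) -> np.ndarray:
    """Gaussian noise with approximate correlation length, unit-calibrated
    so the pointwise standard deviation equals ``sigma``."""
    white = rng.standard_normal(shape)
    if corr_len <= 0 or sigma == 0:
        return sigma * white
    smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return sigma * smooth / sd


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, NoduleMask]:
    """One textured spherical nodule and its base delineation."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    centre = [(n - 1) / 2.0 for n in shape]
    axes = np.indices(shape, dtype=np.float64)
    r = np.sqrt(sum((ax - c) ** 2 for ax, c in zip(axes, centre)))
    mask = r <= spec.nodule_radius

    frac = np.clip(r / spec.nodule_radius, 0.0, 1.0)
    profile = spec.core_hu + (spec.rim_hu - spec.core_hu) * frac
    noise = _correlated_noise(shape, spec.noise_sigma, spec.noise_correlation_length, rng)

    vol = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    vol[mask] = profile[mask] + noise[mask]
    return VoxelVolume(values=vol), NoduleMask(values=mask)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive outside the mask, <= 0 inside (0 on mask voxels)."""
    return ndimage.distance_transform_edt(~mask) - ndimage.distance_transform_edt(mask)


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return np.nan
    return 2.0 * np.logical_and(a, b).sum() / denom


def simulate_raters(base: NoduleMask, model: RaterModel) -> list[NoduleMask]:
    """n_raters plausible delineations of the same nodule.

    Each mask is the base boundary displaced along its normal by a smooth
    random field (std ``boundary_jitter_sigma`` voxels) plus a uniform
    ``dilation_bias`` (negative = erosion).  Masks must be non-empty and
    reach Dice >= min_dice against the base; a failing draw is resampled
    up to a bounded retry count.
    """
    if base.n_voxels == 0:
        raise ValueError("base mask is empty")
    rng = np.random.default_rng(model.seed)
    sd = _signed_distance(base.values)
    masks: list[NoduleMask] = []
    for k in range(model.n_raters):
        for attempt in range(_MAX_RATER_RETRIES):
            if model.boundary_jitter_sigma > 0:
                jitter = _correlated_noise(
                    base.shape, model.boundary_jitter_sigma, JITTER_SMOOTHING_VOXELS, rng
                )
            else:
                jitter = np.zeros(base.shape)
            new = sd <= model.dilation_bias + jitter
            if new.any() and _dice_arrays(new, base.values) >= model.min_dice:
                masks.append(NoduleMask(values=new, spacing=base.spacing))
                break
        else:
            raise RuntimeError(
                f"rater {k}: could not draw a mask with Dice >= {model.min_dice} "
                f"in {_MAX_RATER_RETRIES} attempts (jitter too strong?)"
            )
    return masks


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Per-nodule file paths and seeds, backed by the manifest CSV."""

    frame: pd.DataFrame
    root: Path

    @property
    def n_nodules(self) -> int:
        return len(self.frame)

    @property
    def n_raters(self) -> int:
        return len([c for c in self.frame.columns if c.startswith("mask_rater_")])

    def volume_path(self, idx: int) -> Path:
        return self.root / self.frame.iloc[idx]["volume"]

    def base_mask_path(self, idx: int) -> Path:
        return self.root / self.frame.iloc[idx]["mask_base"]

    def rater_mask_paths(self, idx: int) -> list[Path]:
        cols = [c for c in self.frame.columns if c.startswith("mask_rater_")]
        return [self.root / self.frame.iloc[idx][c] for c in cols]

    def nodule_id(self, idx: int) -> str:
        return str(self.frame.iloc[idx]["nodule_id"])

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path is not None else self.root / "manifest.csv"
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        frame = pd.read_csv(path, dtype={"nodule_id": str})
        manifest = cls(frame=frame, root=path.parent)
        for idx in range(len(frame)):
            for p in [manifest.volume_path(idx), manifest.base_mask_path(idx),
                      *manifest.rater_mask_paths(idx)]:
                if not p.exists():
                    raise FileNotFoundError(f"manifest entry missing on disk: {p}")
        return manifest


def default_spec_sampler(rng: np.random.Generator) -> PhantomSpec:
    """Cohort-level variation: nodule density drawn so that the dataset's
    μ_d ± 2σ_d window derivation is exercised, sizes spanning small to
    medium nodules at ~1 mm voxels."""
    mean_hu = float(rng.normal(-223.0, 180.0))
    contrast = float(rng.uniform(250.0, 450.0))
    radius = float(rng.uniform(4.5, 7.5))
    return PhantomSpec(
        grid_shape=(28, 28, 28),
        nodule_radius=radius,
        core_hu=mean_hu + contrast / 2.0,
        rim_hu=mean_hu - contrast / 2.0,
        noise_sigma=float(rng.uniform(40.0, 80.0)),
        noise_correlation_length=2.0,
        seed=0,  # overwritten with the recorded child seed
    )


def generate_cohort(
    n_nodules: int,
    out_dir: str | Path,
    seed: int,
    spec_sampler: Callable[[np.random.Generator], PhantomSpec] = default_spec_sampler,
    model: RaterModel = RaterModel(),
    image_format: str = "nrrd",
) -> CohortManifest:
    """Generate and write a phantom cohort; returns the manifest.

    ``image_format`` is 'nrrd' (default) or 'nii'.  The master ``seed``
    spawns one recorded child seed per nodule.
    """
    if image_format not in ("nrrd", "nii"):
        raise ValueError(f"unsupported image format {image_format!r}")
    ext = ".nrrd" if image_format == "nrrd" else ".nii"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_nodules)

    rows = []
    for idx in range(n_nodules):
        child = int(child_seeds[idx])
        rng = np.random.default_rng(child)
        spec = replace(spec_sampler(rng), seed=child)
        vol, base = generate_phantom(spec)
        raters = simulate_raters(base, replace(model, seed=child + 1))

        nid = f"nodule_{idx:03d}"
        vol_name = f"{nid}_volume{ext}"
        base_name = f"{nid}_mask_base{ext}"
        try:
            write_image(vol, out_dir / vol_name)
            write_image(base, out_dir / base_name)
            rater_names = []
            for j, m in enumerate(raters, start=1):
                name = f"{nid}_mask_rater_{j}{ext}"
                write_image(m, out_dir / name)
                rater_names.append(name)
        except OSError as exc:
            raise OSError(f"failed writing cohort files for {nid} under {out_dir}: {exc}") from exc

        row = {"nodule_id": nid, "volume": vol_name}
        for j, name in enumerate(rater_names, start=1):
            row[f"mask_rater_{j}"] = name
        row["mask_base"] = base_name
        row["seed"] = child
        rows.append(row)

    columns = ["nodule_id", "volume"] + [
        f"mask_rater_{j}" for j in range(1, model.n_raters + 1)
    ] + ["mask_base", "seed"]
    frame = pd.DataFrame(rows, columns=columns)
    manifest = CohortManifest(frame=frame, root=out_dir)
    manifest.save()
    return manifest
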