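"""Fixed-window clipping and fixed-bin-count intensity quantisation.

The CT signal is clipped to a window ``[ct_min, ct_max]`` derived from the
cohort's nodule densities as μ_d ± 2σ_d (μ_d, σ_d = sample mean and sample
standard deviation of the per-nodule mean HU) and then uniformly quantised
into ``Ng`` grey levels of equal bin width ``(ct_max − ct_min)/Ng``.  Grey
levels are 1-based (1..Ng) to match the conventional indexing of the
grey-level matrix features; the top bin is closed so ``ct_max`` maps to
``Ng``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image import VoxelVolume

#: The absolute CT window used throughout unless re-derived from a cohort.
DEFAULT_CT_MIN = -583.0
DEFAULT_CT_MAX = 137.0

#: Quantisation level counts exercised in the resampling scenario.
DEFAULT_NG_SET = (32, 64, 128, 256)


@dataclass(frozen=True)
class WindowSettings:
    """An absolute HU clipping window, optionally with its derivation.

    ``mu_d``/``sigma_d`` record the cohort statistics the window came from,
    when it was derived rather than supplied.
    """

    ct_min: float = DEFAULT_CT_MIN
    ct_max: float = DEFAULT_CT_MAX
    mu_d: float | None = None
    sigma_d: float | None = None

    def __post_init__(self) -> None:
        if not self.ct_max > self.ct_min:
            raise ValueError(f"invalid window: ct_max={self.ct_max} <= ct_min={self.ct_min}")
        if self.mu_d is not None and self.sigma_d is not None:
            lo, hi = self.mu_d - 2 * self.sigma_d, self.mu_d + 2 * self.sigma_d
            if not (np.isclose(lo, self.ct_min) and np.isclose(hi, self.ct_max)):
                raise ValueError("window bounds inconsistent with mu_d ± 2·sigma_d provenance")

    @property
    def width(self) -> float:
        return self.ct_max - self.ct_min

    @property
    def level(self) -> float:
        return (self.ct_min + self.ct_max) / 2.0


@dataclass(frozen=True)
class QuantisationConfig:
    """Fixed-bin-count quantisation with ``n_levels`` grey levels."""

    n_levels: int = 256

    def __post_init__(self) -> None:
        if int(self.n_levels) != self.n_levels or self.n_levels < 2:
            raise ValueError(f"n_levels must be an integer >= 2, got {self.n_levels}")
        object.__setattr__(self, "n_levels", int(self.n_levels))

    def bin_width(self, w: WindowSettings) -> float:
        return w.width / self.n_levels


def derive_window(mean_densities: Sequence[float]) -> WindowSettings:
    """Derive the μ_d ± 2σ_d window from per-nodule mean densities.

    Uses the n−1 (sample) standard deviation.  Requires at least two
    distinct values; a zero-variance input would give a degenerate window.
    """
    vals = np.asarray(list(mean_densities), dtype=float)
    if vals.size < 2:
        raise ValueError(f"need at least 2 mean densities, got {vals.size}")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    if sigma == 0.0:
        raise ValueError("zero variance in mean densities: degenerate window")
    return WindowSettings(ct_min=mu - 2 * sigma, ct_max=mu + 2 * sigma, mu_d=mu, sigma_d=sigma)


def clip_volume(vol: VoxelVolume, w: WindowSettings) -> VoxelVolume:
    """Clamp intensities to [ct_min, ct_max]; in-range values unchanged."""
    return VoxelVolume(values=np.clip(vol.values, w.ct_min, w.ct_max), spacing=vol.spacing)


@dataclass
class QuantisedVolume:
    """Integer grey levels 1..Ng after clipping + uniform binning."""

    levels: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.levels.shape


def quantise_volume(vol: VoxelVolume, w: WindowSettings, q: QuantisationConfig) -> QuantisedVolume:
    """Map HU values to grey levels: floor((x − ct_min)/bin_width) + 1.

    Bins are left-closed/right-open except the top bin, which is closed so
    that ``x = ct_max`` maps to level Ng.  Clipping is applied internally,
    so quantise(clip(v)) == quantise(v).
    """
    ng = q.n_levels
    x = np.clip(vol.values, w.ct_min, w.ct_max)
    levels = np.floor((x - w.ct_min) / q.bin_width(w)).astype(np.int64) + 1
    np.minimum(levels, ng, out=levels)
    return QuantisedVolume(levels=levels, n_levels=ng, spacing=vol.spacing)


def bin_width_report(w: WindowSettings, n_levels: int) -> int:
    """Bin width in HU rounded to the nearest integer (half away from
    zero, so 22.5 reports as 23), for display only."""
    return int(np.floor(w.width / n_levels + 0.5))
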