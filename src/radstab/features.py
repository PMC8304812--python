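"""The 88 texture features: first-order (13), GLCM (24), GLDM (14),
GLRLM (16), GLSZM (16) and NGTDM (5).

All grey-level matrices are built from a quantised volume (integer levels
1..Ng) restricted to a binary mask, with inter-voxel distance δ=1 and the
full 3D 26-connectivity neighbourhood.  Distances are in voxel units; no
spacing correction is applied (the pipeline performs no spatial
resampling).

Conventions, fixed and deterministic:

* GLCM and GLRLM are built per direction (the 13 unique positive offsets
  of the 26-neighbourhood); features are computed on each non-empty
  direction matrix and then averaged over directions.
* GLCM matrices are symmetrised (counts plus their transpose).
* GLDM: a neighbour is dependent when its level differs from the centre's
  by at most α (default 0).  The matrix column is the raw dependent-
  neighbour count j ∈ {0..26}; features that weight by dependence size use
  j + 1, so a single isolated voxel has small-dependence emphasis 1.
* Degenerate denominators: GLCM Correlation (and MCC) with zero marginal
  variance → 1; IMC1 with zero marginal entropy → 0; NGTDM Coarseness with
  zero denominator → the sentinel 1e6; Busyness and Strength with zero
  denominator → 0.
* A feature that cannot be computed (empty matrix, zero-variance moments)
  is NaN — the explicit "undefined" flag — never silently zero.

First-order Entropy and Uniformity are computed from the quantised level
histogram (hence depend on Ng, with Entropy ∈ [0, log2(Ng)] and
Uniformity ∈ [1/Ng, 1]); the remaining 11 first-order features are
computed from the clipped continuous HU values and are therefore
invariant to Ng.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import NoduleMask, VoxelVolume, check_congruent
from .preprocessing import QuantisationConfig, QuantisedVolume, WindowSettings, clip_volume, quantise_volume

#: Sentinel returned by NGTDM Coarseness when its denominator is zero.
COARSENESS_SENTINEL = 1.0e6

# ---------------------------------------------------------------------------
# Feature census
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = (
    "Entropy", "IQR", "Kurtosis", "MAD", "Max", "Mean", "Median", "Min",
    "Range", "RMAD", "Std", "Skewness", "Uniformity",
)
GLCM_NAMES = (
    "Acorr", "ClShade", "ClProm", "ClTen", "Contr", "Corr", "DiffAvg",
    "DiffEnt", "DiffVar", "JointAvg", "JointEnergy", "JointEntropy",
    "IMC1", "IMC2", "ID", "IDM", "IDMN", "IDN", "InvVar", "MCC",
    "MaxProb", "SumAvg", "SumEnt", "SumSquares",
)
GLDM_NAMES = (
    "DE", "DN", "DNN", "DV", "GLN", "GLV", "HGLE", "LDE", "LDHGLE",
    "LDLGLE", "LGLE", "SDHGLE", "SDLGLE", "SDE",
)
GLRLM_NAMES = (
    "GLNN", "GLN", "GLV", "HGLRE", "LRE", "LRHGLE", "LRLGLE", "LGLRE",
    "RE", "RLNN", "RLN", "RP", "RV", "SRE", "SRHGLE", "SRLGLE",
)
GLSZM_NAMES = (
    "GLN", "GLNN", "GLV", "HGLZE", "LAE", "LAHGLE", "LALGLE", "LGLZE",
    "SZN", "SZNN", "SAE", "SAHGLE", "SALGLE", "ZE", "ZP", "ZV",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

FEATURE_CLASSES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")
_CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

#: Canonical ordered names of all 88 features, class-prefixed because some
#: abbreviations (GLN, GLNN, GLV, Contrast) recur across classes.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cls}_{name}" for cls in FEATURE_CLASSES for name in _CLASS_NAMES[cls]
)

#: The 11 first-order features computed from continuous HU values, hence
#: invariant to the number of quantisation levels.
CONTINUOUS_FIRSTORDER = tuple(
    f"firstorder_{n}" for n in FIRSTORDER_NAMES if n not in ("Entropy", "Uniformity")
)


def feature_class(name: str) -> str:
    cls = name.split("_", 1)[0]
    if cls not in _CLASS_NAMES:
        raise KeyError(f"unknown feature {name!r}")
    return cls


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings: offset distance δ, GLDM threshold α."""

    delta: int = 1
    gldm_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.gldm_alpha < 0:
            raise ValueError("gldm_alpha must be >= 0")

    def digest(self) -> str:
        return hashlib.sha256(f"delta={self.delta};alpha={self.gldm_alpha}".encode()).hexdigest()[:12]


@dataclass
class GreyLevelMatrix:
    """A raw (unnormalised) grey-level count table for one family.

    ``counts`` is indexed by (grey level − 1, second index), where the
    second index is: co-occurring level − 1 (GLCM), dependence size j
    (GLDM), run length − 1 (GLRLM), zone size − 1 (GLSZM).  For NGTDM,
    ``counts`` has two columns: n_i (voxel counts) and s_i (summed
    absolute differences from the neighbourhood mean).
    """

    family: str
    counts: np.ndarray
    direction: tuple[int, int, int] | None = None

    @property
    def is_empty(self) -> bool:
        return float(self.counts.sum()) == 0.0


@dataclass
class FeatureVector:
    """Ordered mapping of the 88 feature names to values for one reading.

    Undefined features are NaN; :attr:`defined` tells them apart.
    """

    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("FeatureVector must contain exactly the 88 canonical features in order")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def defined(self) -> dict[str, bool]:
        return {k: not np.isnan(v) for k, v in self.values.items()}


# The 13 unique direction offsets: the positive half of the 26-neighbourhood.
UNIQUE_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
ALL_NEIGHBOUR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shifted(a: np.ndarray, offset: tuple[int, int, int], fill) -> np.ndarray:
    """Return b with b[v] = a[v + offset], padding with ``fill``."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, o in zip(a.shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_levels(qvol: QuantisedVolume, mask: NoduleMask) -> np.ndarray:
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if qvol.shape != mask.shape:
        raise ValueError(f"shape mismatch: {qvol.shape} vs {mask.shape}")
    return np.where(mask.values, qvol.levels, 0)


# ---------------------------------------------------------------------------
# First-order
# ---------------------------------------------------------------------------

def first_order(
    vol_clipped: VoxelVolume,
    qvol: QuantisedVolume,
    mask: NoduleMask,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> dict[str, float]:
    """The 13 first-order features.

    Entropy/Uniformity come from the quantised level histogram; the other
    11 from the clipped continuous HU values.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    x = vol_clipped.values[mask.values].astype(np.float64)
    lv = qvol.levels[mask.values]

    counts = np.bincount(lv)[1:]
    p = counts[counts > 0] / lv.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    mean = float(np.mean(x))
    m2 = float(np.mean((x - mean) ** 2))
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2 ** 1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2 ** 2)
    else:
        skew = np.nan
        kurt = np.nan
    p10, p25, p75, p90 = np.percentile(x, (10, 25, 75, 90))
    core = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(core - np.mean(core)))) if core.size else np.nan

    out = {
        "Entropy": entropy,
        "IQR": float(p75 - p25),
        "Kurtosis": kurt,
        "MAD": float(np.mean(np.abs(x - mean))),
        "Max": float(np.max(x)),
        "Mean": mean,
        "Median": float(np.median(x)),
        "Min": float(np.min(x)),
        "Range": float(np.max(x) - np.min(x)),
        "RMAD": rmad,
        "Std": float(np.sqrt(m2)),
        "Skewness": skew,
        "Uniformity": uniformity,
    }
    return {f"firstorder_{k}": out[k] for k in FIRSTORDER_NAMES}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def build_glcm(
    qvol: QuantisedVolume, mask: NoduleMask, cfg: ExtractionConfig = ExtractionConfig()
) -> list[GreyLevelMatrix]:
    """One symmetrised co-occurrence matrix per unique direction (13)."""
    lv = _masked_levels(qvol, mask)
    ng = qvol.n_levels
    out = []
    for d in UNIQUE_DIRECTIONS:
        off = tuple(cfg.delta * o for o in d)
        nb = _shifted(lv, off, 0)
        valid = (lv > 0) & (nb > 0)
        i = lv[valid] - 1
        j = nb[valid] - 1
        c = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        out.append(GreyLevelMatrix(family="GLCM", counts=c + c.T, direction=d))
    return out


def _glcm_features_single(p: np.ndarray, ng: int) -> dict[str, float]:
    """The 24 GLCM features on one normalised symmetric matrix."""
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(i @ px)
    uy = float(i @ py)
    sigx = float(np.sqrt(((i - ux) ** 2) @ px))
    sigy = float(np.sqrt(((i - uy) ** 2) @ py))

    ii = i[:, None]
    jj = i[None, :]
    acorr = float((p * ii * jj).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    rows, cols = np.nonzero(p)
    w = p[rows, cols]
    psum = np.bincount(rows + cols, weights=w, minlength=2 * ng - 1)  # index = i+j-2
    pdiff = np.bincount(np.abs(rows - cols), weights=w, minlength=ng)
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kdiff = np.arange(0, ng, dtype=np.float64)

    diff_avg = float(kdiff @ pdiff)
    pd_pos = pdiff[pdiff > 0]
    diff_ent = float(-(pd_pos * np.log2(pd_pos)).sum())
    diff_var = float(((kdiff - diff_avg) ** 2) @ pdiff)

    ps_pos = psum[psum > 0]
    sum_avg = float(ksum @ psum)
    sum_ent = float(-(ps_pos * np.log2(ps_pos)).sum())

    pnz = w
    joint_entropy = float(-(pnz * np.log2(pnz)).sum())
    joint_energy = float((p ** 2).sum())

    px_pos = px[px > 0]
    py_pos = py[py > 0]
    hx = float(-(px_pos * np.log2(px_pos)).sum())
    hy = float(-(py_pos * np.log2(py_pos)).sum())
    pxpy = px[rows] * py[cols]
    hxy1 = float(-(w * np.log2(pxpy)).sum())
    outer = np.outer(px, py)
    outer_pos = outer[outer > 0]
    hxy2 = float(-(outer_pos * np.log2(outer_pos)).sum())
    imc1 = 0.0 if max(hx, hy) == 0 else (joint_entropy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if sigx * sigy > 0:
        corr = (acorr - ux * uy) / (sigx * sigy)
    else:
        corr = 1.0

    # Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), restricted to
    # occupied levels (empty rows only add zero eigenvalues).
    occ = px > 0
    if occ.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(occ, occ)]
        pxs = px[occ]
        pys = py[occ]
        q = (psub @ (psub / pys[None, :]).T) / pxs[:, None]
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))

    return {
        "Acorr": acorr,
        "ClShade": float((p * (ii + jj - ux - uy) ** 3).sum()),
        "ClProm": float((p * (ii + jj - ux - uy) ** 4).sum()),
        "ClTen": float((p * (ii + jj - ux - uy) ** 2).sum()),
        "Contr": float((p * (ii - jj) ** 2).sum()),
        "Corr": float(corr),
        "DiffAvg": diff_avg,
        "DiffEnt": diff_ent,
        "DiffVar": diff_var,
        "JointAvg": ux,
        "JointEnergy": joint_energy,
        "JointEntropy": joint_entropy,
        "IMC1": float(imc1),
        "IMC2": imc2,
        "ID": float((pdiff / (1.0 + kdiff)).sum()),
        "IDM": float((pdiff / (1.0 + kdiff ** 2)).sum()),
        "IDMN": float((pdiff / (1.0 + (kdiff / ng) ** 2)).sum()),
        "IDN": float((pdiff / (1.0 + kdiff / ng)).sum()),
        "InvVar": float((pdiff[1:] / kdiff[1:] ** 2).sum()) if ng > 1 else 0.0,
        "MCC": mcc,
        "MaxProb": float(p.max()),
        "SumAvg": sum_avg,
        "SumEnt": sum_ent,
        "SumSquares": float((p * (ii - ux) ** 2).sum()),
    }


def glcm_features(matrices: list[GreyLevelMatrix]) -> dict[str, float]:
    """24 GLCM features, averaged over non-empty direction matrices."""
    per_dir = []
    for m in matrices:
        if m.is_empty:
            continue
        p = m.counts / m.counts.sum()
        per_dir.append(_glcm_features_single(p, m.counts.shape[0]))
    if not per_dir:
        return {f"glcm_{n}": np.nan for n in GLCM_NAMES}
    return {
        f"glcm_{n}": float(np.mean([d[n] for d in per_dir])) for n in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def build_gldm(
    qvol: QuantisedVolume, mask: NoduleMask, cfg: ExtractionConfig = ExtractionConfig()
) -> GreyLevelMatrix:
    """Dependence matrix: counts(i, j) of in-mask voxels at level i with
    exactly j dependent 26-neighbours (|level difference| <= α)."""
    lv = _masked_levels(qvol, mask)
    ng = qvol.n_levels
    inmask = lv > 0
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in ALL_NEIGHBOUR_OFFSETS:
        off = tuple(cfg.delta * o for o in d)
        nb = _shifted(lv, off, 0)
        dep += (inmask & (nb > 0) & (np.abs(lv - nb) <= cfg.gldm_alpha)).astype(np.int64)
    i = lv[inmask] - 1
    j = dep[inmask]
    ncols = 27
    c = np.bincount(i * ncols + j, minlength=ng * ncols).reshape(ng, ncols).astype(np.float64)
    return GreyLevelMatrix(family="GLDM", counts=c)


def gldm_features(matrix: GreyLevelMatrix) -> dict[str, float]:
    c = matrix.counts
    nz = c.sum()
    if nz == 0:
        return {f"gldm_{n}": np.nan for n in GLDM_NAMES}
    p = c / nz
    ng, ncols = c.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, ncols + 1, dtype=np.float64)[None, :]  # dependence size j+1
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pi).sum())
    mu_j = float((np.arange(1, ncols + 1) * pj).sum())
    pnz = p[p > 0]
    out = {
        "DE": float(-(pnz * np.log2(pnz)).sum()),
        "DN": float((c.sum(axis=0) ** 2).sum() / nz),
        "DNN": float((c.sum(axis=0) ** 2).sum() / nz ** 2),
        "DV": float((p * (jv - mu_j) ** 2).sum()),
        "GLN": float((c.sum(axis=1) ** 2).sum() / nz),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "HGLE": float((p * i ** 2).sum()),
        "LDE": float((p * jv ** 2).sum()),
        "LDHGLE": float((p * i ** 2 * jv ** 2).sum()),
        "LDLGLE": float((p * jv ** 2 / i ** 2).sum()),
        "LGLE": float((p / i ** 2).sum()),
        "SDHGLE": float((p * i ** 2 / jv ** 2).sum()),
        "SDLGLE": float((p / (i ** 2 * jv ** 2)).sum()),
        "SDE": float((p / jv ** 2).sum()),
    }
    return {f"gldm_{n}": out[n] for n in GLDM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def build_glrlm(
    qvol: QuantisedVolume, mask: NoduleMask, cfg: ExtractionConfig = ExtractionConfig()
) -> list[GreyLevelMatrix]:
    """Run-length matrices, one per unique direction (13).

    A run is a maximal collinear sequence of in-mask voxels sharing one
    level; out-of-mask voxels break runs.
    """
    lv = _masked_levels(qvol, mask)
    ng = qvol.n_levels
    max_len = int(np.ceil(np.sqrt(3) * max(lv.shape))) + 1
    out = []
    for d in UNIQUE_DIRECTIONS:
        off = tuple(cfg.delta * o for o in d)
        back = tuple(-o for o in off)
        nxt = _shifted(lv, off, 0)
        prv = _shifted(lv, back, 0)
        inmask = lv > 0
        cont = inmask & (nxt == lv) & (nxt > 0)  # run continues at v -> v+d
        start = inmask & ~((prv == lv) & (prv > 0))
        # forward run length f(v) = 1 + f(v+d) if cont(v): relax until fixed
        f = inmask.astype(np.int64)
        for _ in range(max_len):
            f_new = np.where(cont, 1 + _shifted(f, off, 0), inmask.astype(np.int64))
            if np.array_equal(f_new, f):
                break
            f = f_new
        i = lv[start] - 1
        length = f[start]  # >= 1
        c = np.bincount(i * max_len + (length - 1), minlength=ng * max_len)
        c = c.reshape(ng, max_len).astype(np.float64)
        # trim trailing all-zero length columns (keep at least one column)
        used = np.nonzero(c.sum(axis=0))[0]
        c = c[:, : (used.max() + 1) if used.size else 1]
        out.append(GreyLevelMatrix(family="GLRLM", counts=c, direction=d))
    return out


def _rl_features_single(c: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared run-length / size-zone feature kernel.

    ``kind`` selects the name set: 'glrlm' (runs) or 'glszm' (zones).
    """
    n = c.sum()
    p = c / n
    ng, nl = c.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    l = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_l = float((np.arange(1, nl + 1) * pl).sum())
    pnz = p[p > 0]
    vals = {
        "GLN": float((c.sum(axis=1) ** 2).sum() / n),
        "GLNN": float((c.sum(axis=1) ** 2).sum() / n ** 2),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "HGL": float((p * i ** 2).sum()),
        "LGL": float((p / i ** 2).sum()),
        "LL": float((p * l ** 2).sum()),          # long runs / large areas
        "SS": float((p / l ** 2).sum()),          # short runs / small areas
        "LLHGL": float((p * l ** 2 * i ** 2).sum()),
        "LLLGL": float((p * l ** 2 / i ** 2).sum()),
        "SSHGL": float((p * i ** 2 / l ** 2).sum()),
        "SSLGL": float((p / (i ** 2 * l ** 2)).sum()),
        "LN": float((c.sum(axis=0) ** 2).sum() / n),
        "LNN": float((c.sum(axis=0) ** 2).sum() / n ** 2),
        "PCT": float(n / n_voxels),
        "LV": float((p * (l - mu_l) ** 2).sum()),
        "ENT": float(-(pnz * np.log2(pnz)).sum()),
    }
    if kind == "glrlm":
        return {
            "GLNN": vals["GLNN"], "GLN": vals["GLN"], "GLV": vals["GLV"],
            "HGLRE": vals["HGL"], "LRE": vals["LL"], "LRHGLE": vals["LLHGL"],
            "LRLGLE": vals["LLLGL"], "LGLRE": vals["LGL"], "RE": vals["ENT"],
            "RLNN": vals["LNN"], "RLN": vals["LN"], "RP": vals["PCT"],
            "RV": vals["LV"], "SRE": vals["SS"], "SRHGLE": vals["SSHGL"],
            "SRLGLE": vals["SSLGL"],
        }
    return {
        "GLN": vals["GLN"], "GLNN": vals["GLNN"], "GLV": vals["GLV"],
        "HGLZE": vals["HGL"], "LAE": vals["LL"], "LAHGLE": vals["LLHGL"],
        "LALGLE": vals["LLLGL"], "LGLZE": vals["LGL"], "SZN": vals["LN"],
        "SZNN": vals["LNN"], "SAE": vals["SS"], "SAHGLE": vals["SSHGL"],
        "SALGLE": vals["SSLGL"], "ZE": vals["ENT"], "ZP": vals["PCT"],
        "ZV": vals["LV"],
    }


def glrlm_features(matrices: list[GreyLevelMatrix], n_voxels: int) -> dict[str, float]:
    """16 run-length features per direction, averaged over non-empty ones."""
    per_dir = [
        _rl_features_single(m.counts, n_voxels, "glrlm")
        for m in matrices
        if not m.is_empty
    ]
    if not per_dir:
        return {f"glrlm_{n}": np.nan for n in GLRLM_NAMES}
    return {f"glrlm_{n}": float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def build_glszm(
    qvol: QuantisedVolume, mask: NoduleMask, cfg: ExtractionConfig = ExtractionConfig()
) -> GreyLevelMatrix:
    """Size-zone matrix: counts(i, s) of 26-connected constant-level
    components of level i and size s voxels."""
    lv = _masked_levels(qvol, mask)
    ng = qvol.n_levels
    max_size = int(lv.astype(bool).sum())
    rows: list[int] = []
    sizes: list[int] = []
    for level in np.unique(lv[lv > 0]):
        labels, n_comp = ndimage.label(lv == level, structure=_STRUCT_26)
        if n_comp:
            zone_sizes = np.bincount(labels.ravel())[1:]
            rows.extend([int(level) - 1] * n_comp)
            sizes.extend(int(s) for s in zone_sizes)
    c = np.zeros((ng, max_size), dtype=np.float64)
    for r, s in zip(rows, sizes):
        c[r, s - 1] += 1
    used = np.nonzero(c.sum(axis=0))[0]
    c = c[:, : (used.max() + 1) if used.size else 1]
    return GreyLevelMatrix(family="GLSZM", counts=c)


def glszm_features(matrix: GreyLevelMatrix, n_voxels: int) -> dict[str, float]:
    if matrix.is_empty:
        return {f"glszm_{n}": np.nan for n in GLSZM_NAMES}
    vals = _rl_features_single(matrix.counts, n_voxels, "glszm")
    return {f"glszm_{n}": vals[n] for n in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def build_ngtdm(
    qvol: QuantisedVolume, mask: NoduleMask, cfg: ExtractionConfig = ExtractionConfig()
) -> GreyLevelMatrix:
    """Per level i: n_i = in-mask voxels at level i with >=1 in-mask
    neighbour; s_i = summed |i − mean level of in-mask 26-neighbours|."""
    lv = _masked_levels(qvol, mask)
    ng = qvol.n_levels
    inmask = lv > 0
    nb_sum = np.zeros(lv.shape, dtype=np.float64)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    for d in ALL_NEIGHBOUR_OFFSETS:
        off = tuple(cfg.delta * o for o in d)
        nb = _shifted(lv, off, 0)
        nb_sum += nb
        nb_cnt += (nb > 0).astype(np.int64)
    valid = inmask & (nb_cnt > 0)
    diff = np.zeros(lv.shape, dtype=np.float64)
    diff[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    i = lv[valid] - 1
    n_i = np.bincount(i, minlength=ng).astype(np.float64)
    s_i = np.bincount(i, weights=diff[valid], minlength=ng)
    return GreyLevelMatrix(family="NGTDM", counts=np.column_stack([n_i, s_i]))


def ngtdm_features(matrix: GreyLevelMatrix) -> dict[str, float]:
    n_i = matrix.counts[:, 0]
    s_i = matrix.counts[:, 1]
    nvp = n_i.sum()
    if nvp == 0:
        return {f"ngtdm_{n}": np.nan for n in NGTDM_NAMES}
    p = n_i / nvp
    levels = np.arange(1, len(p) + 1, dtype=np.float64)
    occ = p > 0
    pg, ig, sg = p[occ], levels[occ], s_i[occ]
    ngp = int(occ.sum())

    ps = float((pg * sg).sum())
    coarseness = COARSENESS_SENTINEL if ps == 0 else 1.0 / ps

    if ngp > 1:
        di = ig[:, None] - ig[None, :]
        contrast = float((pg[:, None] * pg[None, :] * di ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(sg.sum()) / nvp
        busy_den = float(np.abs(ig[:, None] * pg[:, None] - ig[None, :] * pg[None, :]).sum())
        busyness = 0.0 if busy_den == 0 else ps / busy_den
        pisi = pg * sg
        complexity = float(
            (np.abs(di) * (pisi[:, None] + pisi[None, :]) / (pg[:, None] + pg[None, :])).sum()
        ) / nvp
        s_tot = float(sg.sum())
        strength = 0.0 if s_tot == 0 else float(
            ((pg[:, None] + pg[None, :]) * di ** 2).sum()
        ) / s_tot
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    out = {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
    return {f"ngtdm_{n}": out[n] for n in NGTDM_NAMES}


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_all(
    vol: VoxelVolume,
    mask: NoduleMask,
    w: WindowSettings = WindowSettings(),
    q: QuantisationConfig = QuantisationConfig(),
    cfg: ExtractionConfig = ExtractionConfig(),
    nodule_id: str | None = None,
    reading_id: str | None = None,
) -> FeatureVector:
    """Clip, quantise and compute all 88 features for one reading."""
    check_congruent(vol, mask)
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    clipped = clip_volume(vol, w)
    qvol = quantise_volume(clipped, w, q)
    n_vox = mask.n_voxels

    values: dict[str, float] = {}
    values.update(first_order(clipped, qvol, mask, cfg))
    values.update(glcm_features(build_glcm(qvol, mask, cfg)))
    values.update(gldm_features(build_gldm(qvol, mask, cfg)))
    values.update(glrlm_features(build_glrlm(qvol, mask, cfg), n_vox))
    values.update(glszm_features(build_glszm(qvol, mask, cfg), n_vox))
    values.update(ngtdm_features(build_ngtdm(qvol, mask, cfg)))

    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(
        values=ordered,
        provenance={
            "nodule_id": nodule_id,
            "reading_id": reading_id,
            "n_levels": q.n_levels,
            "config": cfg.digest(),
        },
    )
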