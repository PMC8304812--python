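"""Feature stability via the average pairwise symmetric MAPE.

For one nodule with readings x_1..x_J of one feature (one reading per
rater, or one per quantisation level), the per-nodule statistic is

    S_i = mean over ordered pairs (f, t) of 100·|x_f − x_t| / (|x_f| + |x_t|)

with the conventional halving of the denominator omitted so S_i ∈ [0, 100].
The summand is written with absolute values so the bound also holds for
negative-valued features (cluster shade, skewness, minimum, IMC1); since
it is then symmetric in its arguments, the ordered-pair mean equals the
unordered-pair mean.  A 0/0 pair (both readings zero) counts as perfect
agreement (0).  The population statistic S is the arithmetic mean of S_i
over nodules; nodules with fewer than two defined readings of a feature
are excluded from that feature's average and counted.

S maps onto a four-grade ordinal scale:
excellent (S ≤ 5), good (5 < S ≤ 10), moderate (10 < S ≤ 20),
poor (20 < S ≤ 100).

Two study designs are provided: scenario A (fixed Ng, one reading per
rater mask — stability to delineation) and scenario B (consensus mask
fixed, one reading per Ng — stability to intensity quantisation, the
quantisation levels playing the role of raters).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusConfig, consolidate
from .features import FEATURE_NAMES, ExtractionConfig, FeatureVector, extract_all, feature_class
from .image import read_mask, read_volume
from .preprocessing import DEFAULT_NG_SET, QuantisationConfig, WindowSettings
from .synthetic import CohortManifest

GRADE_LABELS = ("excellent", "good", "moderate", "poor")
#: Upper bounds (inclusive) of the four stability grades, in percent.
GRADE_BOUNDS = (5.0, 10.0, 20.0, 100.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """The two study designs: A = delineation, B = intensity resampling."""

    scenario: str = "A"
    ng_fixed: int = 256
    ng_set: tuple[int, ...] = DEFAULT_NG_SET
    agreement_level: float = 0.5

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B"):
            raise ValueError("scenario must be 'A' or 'B'")


def smape_pair(x: float, x_hat: float) -> float:
    """100·|x̂ − x| / (|x̂| + |x|); 0 when both readings are 0."""
    if np.isnan(x) or np.isnan(x_hat):
        raise ValueError("undefined reading: pair must be excluded upstream")
    denom = abs(x) + abs(x_hat)
    if denom == 0:
        return 0.0
    # |x̂ − x| <= |x̂| + |x| analytically; clamp the ratio so rounding
    # cannot push the result one ulp past 100
    return 100.0 * min(1.0, abs(x_hat - x) / denom)


def nodule_smape(readings: Sequence[float]) -> float:
    """Mean sMAPE over all ordered pairs of defined readings.

    NaN readings are dropped; fewer than two defined readings raises
    (the nodule must then be excluded and counted by the caller).
    """
    vals = [v for v in readings if not np.isnan(v)]
    if len(vals) < 2:
        raise ValueError(f"need >= 2 defined readings, got {len(vals)}")
    pairs = list(itertools.permutations(vals, 2))
    return float(np.mean([smape_pair(a, b) for a, b in pairs]))


def population_stability(per_nodule: Sequence[float]) -> float:
    """Arithmetic mean of the per-nodule S_i values."""
    vals = list(per_nodule)
    if not vals:
        raise ValueError("no contributing nodules")
    return float(np.mean(vals))


def grade(s: float) -> str:
    """Map S (percent) to the four-grade ordinal stability scale."""
    if np.isnan(s) or not 0 <= s <= 100:
        raise ValueError(f"S must be in [0, 100], got {s}")
    for label, bound in zip(GRADE_LABELS, GRADE_BOUNDS):
        if s <= bound:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------

def stability_table(readings: dict[str, np.ndarray], column: str) -> pd.DataFrame:
    """Aggregate a readings matrix per feature into the stability table.

    ``readings`` maps feature name -> (n_nodules, n_raters) array with NaN
    for undefined readings.  Returns one row per feature: class, S (NaN if
    no nodule contributed), grade, n_nodules_used, n_excluded.
    """
    rows = []
    for name in FEATURE_NAMES:
        mat = readings[name]
        per_nodule = []
        n_excluded = 0
        for i in range(mat.shape[0]):
            defined = mat[i][~np.isnan(mat[i])]
            if defined.size < 2:
                n_excluded += 1
                continue
            per_nodule.append(nodule_smape(defined))
        if per_nodule:
            s = population_stability(per_nodule)
            g = grade(s)
        else:
            s, g = np.nan, "undefined"
        rows.append(
            {
                "feature": name,
                "class": feature_class(name),
                column: s,
                "grade": g,
                "n_nodules_used": len(per_nodule),
                "n_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows)


def _readings_to_matrices(per_nodule_vectors: list[list[FeatureVector]]) -> dict[str, np.ndarray]:
    out = {}
    for name in FEATURE_NAMES:
        out[name] = np.array(
            [[fv[name] for fv in vecs] for vecs in per_nodule_vectors], dtype=float
        )
    return out


def run_scenario_a(
    cohort: CohortManifest,
    w: WindowSettings = WindowSettings(),
    q: QuantisationConfig = QuantisationConfig(256),
    cfg: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Stability to delineation: fixed Ng, one reading per rater mask."""
    vectors = []
    for idx in range(cohort.n_nodules):
        vol = read_volume(cohort.volume_path(idx))
        nid = cohort.nodule_id(idx)
        per_rater = []
        for j, mpath in enumerate(cohort.rater_mask_paths(idx), start=1):
            mask = read_mask(mpath)
            per_rater.append(
                extract_all(vol, mask, w, q, cfg, nodule_id=nid, reading_id=f"rater_{j}")
            )
        if len(per_rater) < 2:
            continue
        vectors.append(per_rater)
    return stability_table(_readings_to_matrices(vectors), "S_delineation")


def run_scenario_b(
    cohort: CohortManifest,
    w: WindowSettings = WindowSettings(),
    ng_set: tuple[int, ...] = DEFAULT_NG_SET,
    agreement_level: float = 0.5,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Stability to quantisation: consensus mask, one reading per Ng."""
    ccfg = ConsensusConfig(agreement_level=agreement_level)
    vectors = []
    for idx in range(cohort.n_nodules):
        vol = read_volume(cohort.volume_path(idx))
        nid = cohort.nodule_id(idx)
        masks = [read_mask(p) for p in cohort.rater_mask_paths(idx)]
        cons = consolidate(masks, ccfg, nodule_id=nid)
        per_ng = [
            extract_all(
                vol, cons, w, QuantisationConfig(ng), cfg,
                nodule_id=nid, reading_id=f"ng_{ng}",
            )
            for ng in ng_set
        ]
        vectors.append(per_ng)
    return stability_table(_readings_to_matrices(vectors), "S_resampling")


def derive_window_from_cohort(
    cohort: CohortManifest, agreement_level: float = 0.5
) -> WindowSettings:
    """μ_d ± 2σ_d window from per-nodule mean density over consensus masks."""
    from .preprocessing import derive_window

    means = []
    for idx in range(cohort.n_nodules):
        vol = read_volume(cohort.volume_path(idx))
        masks = [read_mask(p) for p in cohort.rater_mask_paths(idx)]
        cons = consolidate(masks, ConsensusConfig(agreement_level), cohort.nodule_id(idx))
        means.append(float(vol.values[cons.values].mean()))
    return derive_window(means)
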