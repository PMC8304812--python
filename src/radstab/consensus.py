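"""Consensus consolidation of multiple rater masks by voxel-wise voting.

A voxel belongs to the consensus when at least ``agreement_level`` of the
available delineations include it (>= threshold, ties included).  At the
default 0.5 this is the 50% agreement rule; an agreement level of 1
yields the intersection and any level at or below 1/J the union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import NoduleMask, check_congruent


@dataclass(frozen=True)
class ConsensusConfig:
    agreement_level: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.agreement_level <= 1:
            raise ValueError("agreement_level must be in (0, 1]")


def consolidate(
    masks: list[NoduleMask],
    cfg: ConsensusConfig = ConsensusConfig(),
    nodule_id: str = "?",
) -> NoduleMask:
    """Voxel-wise vote across raters at the configured agreement level."""
    if not masks:
        raise ValueError("need at least one mask")
    check_congruent(masks[0], *masks[1:])
    votes = np.sum([m.values for m in masks], axis=0)
    out = votes / len(masks) >= cfg.agreement_level
    if not out.any():
        raise ValueError(f"empty consensus for nodule {nodule_id}")
    return NoduleMask(values=out, spacing=masks[0].spacing)


def dice(a: NoduleMask, b: NoduleMask) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|); NaN when both masks are empty."""
    check_congruent(a, b)
    denom = a.n_voxels + b.n_voxels
    if denom == 0:
        return float("nan")
    return 2.0 * float(np.logical_and(a.values, b.values).sum()) / denom
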