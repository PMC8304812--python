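"""Independent brute-force enumerators for the grey-level matrices.

Deliberately naive (nested loops, dict counters, explicit BFS) so they
share no code path with the vectorised builders they check.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque

import numpy as np

NEIGHBOURS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def bf_glcm(levels: np.ndarray, mask: np.ndarray, direction) -> Counter:
    """Symmetrised co-occurrence counts {(i, j): count} for one offset."""
    out: Counter = Counter()
    for v in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[v]:
            continue
        w = tuple(c + d for c, d in zip(v, direction))
        if _inside(levels.shape, w) and mask[w]:
            out[(int(levels[v]), int(levels[w]))] += 1
            out[(int(levels[w]), int(levels[v]))] += 1
    return out


def bf_gldm(levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0) -> Counter:
    """Dependence counts {(level, n_dependent_neighbours): count}."""
    out: Counter = Counter()
    for v in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[v]:
            continue
        dep = 0
        for d in NEIGHBOURS_26:
            w = tuple(c + o for c, o in zip(v, d))
            if _inside(levels.shape, w) and mask[w] and abs(int(levels[v]) - int(levels[w])) <= alpha:
                dep += 1
        out[(int(levels[v]), dep)] += 1
    return out


def bf_glrlm(levels: np.ndarray, mask: np.ndarray, direction) -> Counter:
    """Run counts {(level, run_length): count} for one direction."""
    out: Counter = Counter()
    for v in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[v]:
            continue
        prev = tuple(c - d for c, d in zip(v, direction))
        if _inside(levels.shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(c + d for c, d in zip(cur, direction))
            if _inside(levels.shape, nxt) and mask[nxt] and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        out[(int(levels[v]), length)] += 1
    return out


def bf_glszm(levels: np.ndarray, mask: np.ndarray) -> Counter:
    """Zone counts {(level, zone_size): count} under 26-connectivity."""
    out: Counter = Counter()
    seen = np.zeros(levels.shape, dtype=bool)
    for v in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[v] or seen[v]:
            continue
        lvl = int(levels[v])
        queue = deque([v])
        seen[v] = True
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for d in NEIGHBOURS_26:
                w = tuple(c + o for c, o in zip(cur, d))
                if _inside(levels.shape, w) and mask[w] and not seen[w] and int(levels[w]) == lvl:
                    seen[w] = True
                    queue.append(w)
        out[(lvl, size)] += 1
    return out


def bf_ngtdm(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Per level i: {'n': voxel count with >=1 in-mask neighbour, 's': sum
    of |i - mean neighbour level|}."""
    out: dict = {}
    for v in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[v]:
            continue
        nb = []
        for d in NEIGHBOURS_26:
            w = tuple(c + o for c, o in zip(v, d))
            if _inside(levels.shape, w) and mask[w]:
                nb.append(int(levels[w]))
        if not nb:
            continue
        lvl = int(levels[v])
        entry = out.setdefault(lvl, {"n": 0, "s": 0.0})
        entry["n"] += 1
        entry["s"] += abs(lvl - sum(nb) / len(nb))
    return out
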