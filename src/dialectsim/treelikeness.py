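"""Quartet-based δ score: deviation of a distance matrix from tree additivity.

For four taxa x, y, u, v the three pairings of pairwise-distance sums
d_xy + d_uv, d_xu + d_yv, d_xv + d_yu are sorted as s₁ ≤ s₂ ≤ s₃ and the
quartet's score is δ = (s₃ − s₂)/(s₃ − s₁), which lies in [0, 1]; on an
additive (tree) metric the two largest sums coincide and δ = 0.  A quartet
whose three sums are all equal (a star metric) is scored 0 by convention.
The overall δ score is the mean over quartets — all C(n, 4) of them by
default, or a uniform random subsample for large n.  Lower values mean more
tree-like data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from random import Random

import numpy as np

from .lexicon import DistanceMatrix

__all__ = ["DeltaResult", "delta_quartet", "delta_score"]

#: relative tolerance for detecting the all-sums-equal (star) quartet
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class DeltaResult:
    """Summary of quartet δ values over a distance matrix.

    ``mode`` is "exhaustive" or "subsampled"; ``per_taxon`` holds, for each
    taxon, the mean δ over the evaluated quartets containing it.
    """

    mean_delta: float
    n_quartets: int
    per_taxon: dict[str, float]
    mode: str
    subsample_k: int | None = None
    subsample_seed: int | None = None


def _quartet_value(d: np.ndarray, x: int, y: int, u: int, v: int) -> float:
    s1 = d[x, y] + d[u, v]
    s2 = d[x, u] + d[y, v]
    s3 = d[x, v] + d[y, u]
    lo, mid, hi = sorted((s1, s2, s3))
    if hi - lo <= _TIE_RTOL * max(abs(hi), abs(lo), 1e-300):
        return 0.0
    return (hi - mid) / (hi - lo)


def delta_quartet(dm: DistanceMatrix, x: str, y: str, u: str, v: str) -> float:
    """δ of a single quartet of distinct taxa."""
    names = (x, y, u, v)
    if len(set(names)) != 4:
        raise ValueError("quartet taxa must be distinct")
    idx = [dm.taxa.index(n) for n in names]
    return _quartet_value(dm.values, *idx)


def _unrank_quartet(rank: int, n: int) -> tuple[int, int, int, int]:
    """Map a lexicographic rank in [0, C(n,4)) to a 4-combination of range(n)."""
    out = []
    prev = -1
    remaining = 4
    for _ in range(4):
        i = prev + 1
        while True:
            block = comb(n - 1 - i, remaining - 1)
            if rank < block:
                break
            rank -= block
            i += 1
        out.append(i)
        prev = i
        remaining -= 1
    return tuple(out)


def delta_score(
    dm: DistanceMatrix,
    subsample: tuple[int, int] | None = None,
) -> DeltaResult:
    """Mean quartet δ over a distance matrix.

    Parameters
    ----------
    dm
        Symmetric distance matrix over >= 4 taxa.
    subsample
        Optional ``(k, seed)``: average over k distinct quartets sampled
        uniformly without replacement instead of all C(n, 4).  Intended for
        large n; k = C(n, 4) recovers the exhaustive quartet set.
    """
    n = len(dm.taxa)
    if n < 4:
        raise ValueError("delta score needs at least 4 taxa")
    d = dm.values
    totals = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)

    if subsample is None:
        quartets = combinations(range(n), 4)
        mode = "exhaustive"
        k = seed = None
    else:
        k, seed = subsample
        total_q = comb(n, 4)
        if not 1 <= k <= total_q:
            raise ValueError(f"subsample size must be in [1, C(n,4)] = [1, {total_q}]")
        rng = Random(seed)
        ranks = rng.sample(range(total_q), k)
        quartets = [_unrank_quartet(r, n) for r in ranks]
        mode = "subsampled"

    total = 0.0
    m = 0
    for q in quartets:
        val = _quartet_value(d, *q)
        total += val
        m += 1
        for i in q:
            totals[i] += val
            counts[i] += 1
    per_taxon = {
        t: (totals[i] / counts[i] if counts[i] else float("nan"))
        for i, t in enumerate(dm.taxa)
    }
    assert subsample is not None or m == comb(n, 4)
    return DeltaResult(
        mean_delta=total / m,
        n_quartets=m,
        per_taxon=per_taxon,
        mode=mode,
        subsample_k=k,
        subsample_seed=seed,
    )
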