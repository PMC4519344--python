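"""Binary character matrices, Hamming-ratio distances and survival times.

The final simulation snapshot is encoded the way a basic-vocabulary field
study would record it: one binary column per cognate that survives to the
end, grouped by concept, with a 1 where a dialect holds the cognate.  The
distance between two dialects is the ratio of mismatching digits between
their binary vectors.  Extinct cognates leave no column — only the current
snapshot of distributions is observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import CognateRegistry, SimulationResult

__all__ = [
    "CognateMatrix",
    "DistanceMatrix",
    "encode_binary",
    "distance_matrix",
    "survival_times",
]


@dataclass(frozen=True)
class CognateMatrix:
    """Taxa × cognate presence/absence matrix, columns grouped by concept.

    ``columns[k]`` is the (concept index, cognate id) pair of column k; the
    data are 0/1 uint8.
    """

    taxa: tuple[str, ...]
    columns: tuple[tuple[int, int], ...]
    data: np.ndarray

    def __post_init__(self):
        if self.data.shape != (len(self.taxa), len(self.columns)):
            raise ValueError("matrix shape does not match taxa/columns")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.columns)

    def concept_blocks(self) -> dict[int, tuple[int, int]]:
        """Half-open column ranges [start, stop) per concept index."""
        blocks: dict[int, tuple[int, int]] = {}
        for k, (concept, _) in enumerate(self.columns):
            if concept not in blocks:
                blocks[concept] = (k, k + 1)
            else:
                start, _ = blocks[concept]
                blocks[concept] = (start, k + 1)
        return blocks

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"c{concept}_{cid}" for concept, cid in self.columns]
        return pd.DataFrame(self.data, index=list(self.taxa), columns=cols)

    def row_string(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join("1" if x else "0" for x in self.data[i])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over taxa")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))


def encode_binary(result: SimulationResult) -> CognateMatrix:
    """Encode the final snapshot as a binary matrix, one column per
    surviving cognate.

    Column order is deterministic: concept index, then birth time, then
    cognate id.  A column exists iff the cognate is held by at least one
    taxon at the end, so every (taxon, concept) block has at least one 1.
    """
    taxa = result.taxa
    columns: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    col_chunks: list[np.ndarray] = []
    for concept, (final, registry) in enumerate(
        zip(result.states, result.registries)
    ):
        present: set[int] = set()
        for v in final.values():
            present.update(v)
        ordered = sorted(
            present, key=lambda cid: (registry[cid].birth_time, cid)
        )
        block = np.zeros((len(taxa), len(ordered)), dtype=np.uint8)
        col_of = {cid: k for k, cid in enumerate(ordered)}
        for r, taxon in enumerate(taxa):
            for cid in final[taxon]:
                block[r, col_of[cid]] = 1
        col_chunks.append(block)
        columns.extend((concept, cid) for cid in ordered)
    data = np.hstack(col_chunks) if col_chunks else np.zeros((len(taxa), 0), np.uint8)
    return CognateMatrix(tuple(taxa), tuple(columns), data)


def distance_matrix(matrix: CognateMatrix) -> DistanceMatrix:
    """Hamming-ratio distances: mismatching digits / total columns."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least two taxa")
    if matrix.n_chars == 0:
        raise ValueError("matrix has no characters")
    x = matrix.data.astype(np.int16)
    # pairwise Hamming counts via broadcasting; matrices are small
    diff = (x[:, None, :] != x[None, :, :]).sum(axis=2)
    values = diff / matrix.n_chars
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(matrix.taxa, values)


def survival_times(
    registries: Iterable[CognateRegistry] | CognateRegistry, T: int | None = None
) -> list[int]:
    """Lifespans (death − birth, in steps) of all transient cognates.

    The shared initial cognate and cognates still alive at the end are
    excluded: only words both born and dead inside the observation window
    have a well-defined survival time.
    """
    if isinstance(registries, CognateRegistry):
        registries = [registries]
    out: list[int] = []
    for registry in registries:
        for rec in registry:
            if rec.birth_time == 0 or rec.death_time is None:
                continue
            out.append(rec.death_time - rec.birth_time)
    return out
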