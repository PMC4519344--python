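"""Readers and writers for the standard interchange formats.

Binary cognate matrices are exported as NEXUS (datatype=standard, symbols
"01", one CHARSET per concept) so that split-network and Bayesian
phylogenetics tools can consume them directly; distance matrices go out as
PHYLIP square matrices or CSV; the birth/death ledger as CSV.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dynamics import CognateRegistry, SimulationResult
from .lexicon import CognateMatrix, DistanceMatrix

__all__ = [
    "write_nexus",
    "read_nexus_matrix",
    "write_phylip",
    "read_phylip",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_distance_csv",
    "write_registry_csv",
]

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+-]+$")


def _nexus_label(label: str) -> str:
    """Quote a taxon label when it contains characters NEXUS reserves."""
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: CognateMatrix, path: str | Path) -> Path:
    """Write a binary character matrix as a NEXUS DATA block.

    Includes a SETS block with one CHARSET per concept so downstream tools
    can see the concept structure.  Raises on an empty matrix.
    """
    if matrix.n_taxa == 0 or matrix.n_chars == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    width = max(len(_nexus_label(t)) for t in matrix.taxa)
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        row = "".join("1" if x else "0" for x in matrix.data[i])
        lines.append(f"        {_nexus_label(taxon):<{width}}  {row}")
    lines.append("    ;")
    lines.append("END;")
    blocks = matrix.concept_blocks()
    if blocks:
        lines.append("")
        lines.append("BEGIN SETS;")
        for concept, (start, stop) in sorted(blocks.items()):
            lines.append(
                f"    CHARSET concept_{concept} = {start + 1}-{stop};"
            )
        lines.append("END;")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_nexus_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read taxa and the 0/1 matrix back from a NEXUS standard-data file."""
    import dendropy

    chars = dendropy.StandardCharacterMatrix.get(
        path=str(path), schema="nexus"
    )
    taxa = tuple(t.label for t in chars.taxon_namespace)
    rows = []
    for taxon in chars.taxon_namespace:
        seq = chars[taxon]
        rows.append([int(str(s)) for s in seq])
    return taxa, np.asarray(rows, dtype=np.uint8)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> Path:
    """Write a square PHYLIP distance matrix (relaxed labels, 6 decimals)."""
    path = Path(path)
    n = len(dm.taxa)
    width = max(10, max(len(t) for t in dm.taxa) + 2)
    with path.open("w") as fh:
        fh.write(f"{n}\n")
        for i, taxon in enumerate(dm.taxa):
            vals = " ".join(f"{dm.values[i, j]:.6f}" for j in range(n))
            fh.write(f"{taxon:<{width}}{vals}\n")
    return path


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    taxa: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(tuple(taxa), np.asarray(rows, dtype=float))


def write_matrix_csv(matrix: CognateMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_dataframe().to_csv(path, index_label="taxon")
    return path


def read_matrix_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a taxa × binary-characters CSV (taxa in the first column)."""
    df = pd.read_csv(path, index_col=0)
    return tuple(str(t) for t in df.index), df.to_numpy(dtype=np.uint8)


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    dm.to_dataframe().to_csv(path, index_label="taxon")
    return path


def write_registry_csv(
    registries: Iterable[CognateRegistry] | CognateRegistry, path: str | Path
) -> Path:
    """Dump the birth/death ledger: one row per cognate ever born."""
    if isinstance(registries, CognateRegistry):
        registries = [registries]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["concept", "cognate_id", "birth_node", "birth_time", "death_time"]
        )
        for registry in registries:
            for rec in registry:
                writer.writerow(
                    [
                        rec.concept,
                        rec.cognate_id,
                        rec.birth_node if rec.birth_node is not None else "",
                        rec.birth_time,
                        rec.death_time if rec.death_time is not None else "alive",
                    ]
                )
    return path
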