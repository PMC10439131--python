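"""Staggered hexagonal spot lattices.

Spots live on a Visium-style staggered grid: a spot exists at integer
``(array_row, array_col)`` only when row and column share parity, which
packs the spots hexagonally.  Each interior spot touches six others:
``(row, col +/- 2)`` and ``(row +/- 1, col +/- 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: offsets of the six directly adjacent spots on the staggered grid
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


def generate_hex_lattice(n_rows: int, n_cols: int) -> pd.DataFrame:
    """Enumerate all spots of an ``n_rows x n_cols`` staggered hex grid.

    Returns a DataFrame indexed by ``spot_id`` with columns
    ``array_row``, ``array_col`` and ``in_tissue`` (all True).  Only
    (row, col) pairs with matching parity host a spot.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    keep = (rows % 2) == (cols % 2)
    rows, cols = rows[keep], cols[keep]
    spot_ids = [f"spot_{r}x{c}" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {"array_row": rows, "array_col": cols, "in_tissue": True},
        index=pd.Index(spot_ids, name="spot_id"),
    )


def axial_coords(array_row, array_col):
    """Map staggered (row, col) to axial hex coordinates (q, r)."""
    array_row = np.asarray(array_row)
    array_col = np.asarray(array_col)
    q = (array_col - array_row) // 2
    return q, array_row


def hex_distance(row_a, col_a, row_b, col_b):
    """Hex (ring) distance between two spots on the staggered grid."""
    qa, ra = axial_coords(row_a, col_a)
    qb, rb = axial_coords(row_b, col_b)
    dq, dr = qa - qb, ra - rb
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2


def hex_neighbors(lattice: pd.DataFrame, spot_id: str) -> list[str]:
    """Spot ids of the up-to-six in-tissue spots directly in contact."""
    if spot_id not in lattice.index:
        raise KeyError(f"unknown spot {spot_id!r}")
    row = int(lattice.at[spot_id, "array_row"])
    col = int(lattice.at[spot_id, "array_col"])
    lookup = _position_index(lattice)
    out = []
    for dr, dc in HEX_OFFSETS:
        hit = lookup.get((row + dr, col + dc))
        if hit is not None:
            out.append(hit)
    return out


def neighbor_table(lattice: pd.DataFrame) -> dict[str, list[str]]:
    """Adjacency lists for every in-tissue spot of the lattice."""
    lookup = _position_index(lattice)
    table: dict[str, list[str]] = {}
    for spot_id, row, col in zip(
        lattice.index, lattice["array_row"], lattice["array_col"]
    ):
        if not lattice.at[spot_id, "in_tissue"]:
            continue
        table[spot_id] = [
            lookup[(row + dr, col + dc)]
            for dr, dc in HEX_OFFSETS
            if (row + dr, col + dc) in lookup
        ]
    return table


def _position_index(lattice: pd.DataFrame) -> dict[tuple[int, int], str]:
    tissue = lattice[lattice["in_tissue"]]
    return {
        (int(r), int(c)): sid
        for sid, r, c in zip(tissue.index, tissue["array_row"], tissue["array_col"])
    }
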