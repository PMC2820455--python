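"""Screening plate layouts.

A plate map assigns every well of every physical plate a role: a target
siRNA, a non-silencing (NS) control, or empty. The screen design mirrors a
kinome library screen: each gene is covered by a fixed number of distinct
siRNAs, every siRNA is assayed in triplicate (one well on each of three
replicate plates sharing a layout), and every physical plate carries its own
triplicate of NS control wells that later anchor the normalization.

Plate maps are plain pandas DataFrames with columns
``plate_id, layout, replicate, well, role, gene, sirna_id``.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from ._seeds import substream

__all__ = [
    "ROLE_TARGET",
    "ROLE_CONTROL",
    "ROLE_EMPTY",
    "PlateCapacityError",
    "make_platemap",
    "well_names",
    "read_platemap",
    "write_platemap",
]

ROLE_TARGET = "target"
ROLE_CONTROL = "non_silencing"
ROLE_EMPTY = "empty"

PLATEMAP_COLUMNS = ["plate_id", "layout", "replicate", "well", "role", "gene", "sirna_id"]

#: standard microtiter footprints (wells -> rows x columns)
_PLATE_SHAPES = {6: (2, 3), 12: (3, 4), 24: (4, 6), 48: (6, 8), 96: (8, 12), 384: (16, 24)}


class PlateCapacityError(ValueError):
    """Requested layout does not fit the allowed number of plates."""


def well_names(wells_per_plate: int) -> list[str]:
    """Well labels ("A01".."H12" for 96) in row-major plate order."""
    if wells_per_plate in _PLATE_SHAPES:
        n_rows, n_cols = _PLATE_SHAPES[wells_per_plate]
    else:
        n_cols = min(12, wells_per_plate)
        n_rows = math.ceil(wells_per_plate / n_cols)
    names = [
        f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)
    ]
    return names[:wells_per_plate]


def make_platemap(
    genes: int | Sequence[str],
    sirnas_per_gene: int = 2,
    replicates: int = 3,
    controls_per_plate: int = 3,
    wells_per_plate: int = 96,
    seed: int = 0,
    max_plates: int | None = None,
) -> pd.DataFrame:
    """Lay out a full screen as a plate-map table.

    siRNAs are packed onto as many plate layouts as needed; each layout is
    replicated ``replicates`` times as physical plates (``plate_id`` =
    ``P{layout}r{replicate}``), so each siRNA lands on ``replicates`` wells
    and every physical plate carries exactly ``controls_per_plate`` NS wells.
    Well positions (including the control positions, per layout) are a
    seeded permutation; the result is deterministic given ``seed``.

    Raises
    ------
    PlateCapacityError
        if ``max_plates`` is given and the design does not fit.
    """
    if isinstance(genes, int):
        if genes <= 0:
            raise ValueError("need at least one gene")
        gene_names = [f"GENE{i + 1:04d}" for i in range(genes)]
    else:
        gene_names = list(genes)
        if not gene_names:
            raise ValueError("need at least one gene")
    if sirnas_per_gene <= 0 or replicates <= 0 or controls_per_plate < 0:
        raise ValueError("counts must be positive")
    if wells_per_plate < controls_per_plate + 1:
        raise ValueError("plate must hold the NS controls plus at least one target well")

    sirnas = [(g, f"{g}_s{j + 1}") for g in gene_names for j in range(sirnas_per_gene)]
    capacity = wells_per_plate - controls_per_plate
    n_layouts = math.ceil(len(sirnas) / capacity)
    if max_plates is not None and n_layouts * replicates > max_plates:
        raise PlateCapacityError(
            f"{len(sirnas)} siRNAs x {replicates} replicates need "
            f"{n_layouts * replicates} plates, cap is {max_plates}"
        )

    rng = substream(seed, "platemap")
    order = rng.permutation(len(sirnas))
    names = well_names(wells_per_plate)

    rows: list[tuple] = []
    for layout in range(1, n_layouts + 1):
        chunk = [sirnas[i] for i in order[(layout - 1) * capacity : layout * capacity]]
        pos = rng.permutation(wells_per_plate)
        control_pos = set(pos[:controls_per_plate].tolist())
        target_pos = [p for p in pos[controls_per_plate:].tolist()][: len(chunk)]
        occupied = {p: ("__target__", i) for i, p in enumerate(target_pos)}
        for rep in range(1, replicates + 1):
            plate_id = f"P{layout:02d}r{rep}"
            for p in range(wells_per_plate):
                if p in control_pos:
                    rows.append((plate_id, layout, rep, names[p], ROLE_CONTROL, "NS", "NS"))
                elif p in occupied:
                    gene, sid = chunk[occupied[p][1]]
                    rows.append((plate_id, layout, rep, names[p], ROLE_TARGET, gene, sid))
                else:
                    rows.append((plate_id, layout, rep, names[p], ROLE_EMPTY, "", ""))
    pm = pd.DataFrame(rows, columns=PLATEMAP_COLUMNS)
    # sanity: the design invariants the rest of the pipeline relies on
    n_target = int((pm["role"] == ROLE_TARGET).sum())
    assert n_target == len(sirnas) * replicates
    assert (
        pm[pm["role"] == ROLE_CONTROL].groupby("plate_id").size() == controls_per_plate
    ).all() or controls_per_plate == 0
    return pm


def write_platemap(pm: pd.DataFrame, path) -> None:
    pm.to_csv(path, index=False)


def read_platemap(path) -> pd.DataFrame:
    pm = pd.read_csv(path, dtype={"gene": str, "sirna_id": str}, keep_default_na=False)
    missing = set(PLATEMAP_COLUMNS) - set(pm.columns)
    if missing:
        raise ValueError(f"plate map is missing columns: {sorted(missing)}")
    return pm
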