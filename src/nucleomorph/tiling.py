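"""Slide tiling and merging of per-tile segmentation results.

Whole-slide images are processed as non-overlapping tiles (4096 x 4096 by
default; edge tiles smaller).  Per-tile label maps and feature tables are
merged into a single global nucleus table: labels are re-keyed to globally
unique ids, centroids shifted by the tile origin, and nuclei touching a
shared tile edge are flagged as border objects and deduplicated.

Border policy: two border records from adjacent tiles whose contact
intervals on the shared edge overlap are fragments of one straddling
nucleus; the fragment containing the merged centroid (the larger fragment
for convex nuclei) survives.  Independently, records whose global centroids
fall within 2 px of each other across a shared edge are treated as exact
duplicates and collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TileIndex", "tile_plan", "merge_tile_results"]

DEFAULT_TILE_SIZE = 4096
DUPLICATE_CENTROID_PX = 2.0


@dataclass(frozen=True)
class TileIndex:
    """Grid position and pixel extent of one tile."""

    slide_id: str
    tile_row: int
    tile_col: int
    origin: tuple[int, int]  # global (row, col) of the tile's top-left pixel
    size: tuple[int, int]  # (rows, cols)


def tile_plan(
    slide_dims: tuple[int, int],
    tile_size: int = DEFAULT_TILE_SIZE,
    slide_id: str = "slide",
) -> list[TileIndex]:
    """Row-major non-overlapping cover of a slide; edge tiles are smaller."""
    rows, cols = slide_dims
    if rows <= 0 or cols <= 0:
        raise ValueError("slide dimensions must be positive")
    plan = []
    for tr, r0 in enumerate(range(0, rows, tile_size)):
        for tc, c0 in enumerate(range(0, cols, tile_size)):
            plan.append(
                TileIndex(
                    slide_id=slide_id,
                    tile_row=tr,
                    tile_col=tc,
                    origin=(r0, c0),
                    size=(min(tile_size, rows - r0), min(tile_size, cols - c0)),
                )
            )
    return plan


def _edge_contacts(labels: np.ndarray) -> dict[str, dict[int, tuple[int, int]]]:
    """For each tile edge, the contact interval (min, max position along the
    edge) of every label touching it."""
    out: dict[str, dict[int, tuple[int, int]]] = {}
    edges = {
        "top": labels[0, :],
        "bottom": labels[-1, :],
        "left": labels[:, 0],
        "right": labels[:, -1],
    }
    for name, line in edges.items():
        contacts: dict[int, tuple[int, int]] = {}
        for lab in np.unique(line):
            if lab <= 0:
                continue
            pos = np.nonzero(line == lab)[0]
            contacts[int(lab)] = (int(pos.min()), int(pos.max()))
        out[name] = contacts
    return out


def merge_tile_results(
    results: dict[TileIndex, tuple[np.ndarray, pd.DataFrame]],
    plan: list[TileIndex],
) -> pd.DataFrame:
    """Merge per-tile label maps and feature tables into a global table.

    ``results`` maps each planned tile to its ``(LabelMap, feature_table)``
    where the table carries per-tile ``label``, ``centroid_row`` and
    ``centroid_col`` columns.  The output adds ``global_id``, ``tile_row``,
    ``tile_col`` and a ``border`` flag, with centroids in global coordinates.
    Missing tiles raise an error listing the gaps.  The merge is independent
    of tile processing order.
    """
    missing = [t for t in plan if t not in results]
    if missing:
        gaps = ", ".join(f"({t.tile_row},{t.tile_col})" for t in missing)
        raise ValueError(f"missing tile results for: {gaps}")

    by_grid = {(t.tile_row, t.tile_col): t for t in plan}
    frames = []
    contacts_by_tile = {}
    for t in plan:
        labels, table = results[t]
        contacts_by_tile[(t.tile_row, t.tile_col)] = _edge_contacts(labels)
        tab = table.copy()
        tab["tile_row"] = t.tile_row
        tab["tile_col"] = t.tile_col
        tab["centroid_row"] = tab["centroid_row"] + t.origin[0]
        tab["centroid_col"] = tab["centroid_col"] + t.origin[1]
        con = contacts_by_tile[(t.tile_row, t.tile_col)]
        border_labels = set()
        # only edges shared with another planned tile count as border edges
        if (t.tile_row - 1, t.tile_col) in by_grid:
            border_labels |= set(con["top"])
        if (t.tile_row + 1, t.tile_col) in by_grid:
            border_labels |= set(con["bottom"])
        if (t.tile_row, t.tile_col - 1) in by_grid:
            border_labels |= set(con["left"])
        if (t.tile_row, t.tile_col + 1) in by_grid:
            border_labels |= set(con["right"])
        tab["border"] = tab["label"].astype(int).isin(border_labels)
        frames.append(tab)
    merged = pd.concat(frames, ignore_index=True).sort_values(
        ["tile_row", "tile_col", "label"], kind="stable", ignore_index=True
    )
    merged.insert(0, "global_id", np.arange(1, len(merged) + 1))

    drop: set[int] = set()
    # straddle resolution along shared horizontal and vertical edges
    for t in plan:
        key = (t.tile_row, t.tile_col)
        for neigh_key, edge_here, edge_there in (
            ((t.tile_row + 1, t.tile_col), "bottom", "top"),
            ((t.tile_row, t.tile_col + 1), "right", "left"),
        ):
            if neigh_key not in by_grid:
                continue
            here = contacts_by_tile[key][edge_here]
            there = contacts_by_tile[neigh_key][edge_there]
            for lab_a, (a0, a1) in here.items():
                for lab_b, (b0, b1) in there.items():
                    if a0 <= b1 and b0 <= a1:  # contact intervals overlap
                        ra = merged[
                            (merged.tile_row == key[0]) & (merged.tile_col == key[1])
                            & (merged.label == lab_a)
                        ]
                        rb = merged[
                            (merged.tile_row == neigh_key[0]) & (merged.tile_col == neigh_key[1])
                            & (merged.label == lab_b)
                        ]
                        if ra.empty or rb.empty:
                            continue
                        ra, rb = ra.iloc[0], rb.iloc[0]
                        # centroid-ownership: the fragment containing the
                        # area-weighted merged centroid survives
                        loser = rb if ra.get("Area", 1.0) >= rb.get("Area", 1.0) else ra
                        drop.add(int(loser.global_id))
    # exact-duplicate suppression by centroid proximity among border records
    border = merged[merged.border & ~merged.global_id.isin(drop)]
    coords = border[["centroid_row", "centroid_col"]].to_numpy()
    ids = border["global_id"].to_numpy()
    tiles = border[["tile_row", "tile_col"]].to_numpy()
    for i in range(len(border)):
        for j in range(i + 1, len(border)):
            if (tiles[i] == tiles[j]).all():
                continue
            if np.hypot(*(coords[i] - coords[j])) < DUPLICATE_CENTROID_PX:
                drop.add(int(ids[j]))
    return merged[~merged.global_id.isin(drop)].reset_index(drop=True)
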