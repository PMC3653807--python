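"""Environmental raster stacks, feature extraction and the collinearity screen.

The modelling pipeline works on a stack of aligned single-band rasters
(one per environmental predictor) sharing one grid and one nodata mask.
Before any model is fitted the predictor set is screened for pairwise
collinearity: layers are retained only if every pairwise Pearson
correlation satisfies ``|r| < cutoff`` (default 0.7), dropping from each
offending pair the layer most correlated with the rest on average.

Grid convention: 0-based ``(row, col)`` indices with row 0 at the north
edge; planar equal-area coordinates; cell centers are used for all
distances.  Nodata is carried as a shared boolean mask rather than a
sentinel value so that correlations and extractions are computed over
valid cells only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sdmeval")

ASCII_NODATA = -9999.0


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """Aligned multi-layer raster grid of environmental predictors.

    Parameters
    ----------
    layer_names
        One identifier per layer, unique.
    values
        Array of shape ``(n_layers, rows, cols)``.
    cell_size_km
        Edge length of a (square) cell in km; 1.0 emulates a 1 km^2 grid.
    nodata_mask
        Boolean ``(rows, cols)`` array, ``True`` where cells carry no data.
        Shared by every layer.
    """

    layer_names: list[str]
    values: np.ndarray
    cell_size_km: float = 1.0
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_layers, rows, cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.layer_names)} layer names for "
                f"{self.values.shape[0]} layers"
            )
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise ValueError("nodata_mask shape must match the grid shape")

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_cells(self) -> np.ndarray:
        """All valid ``(row, col)`` indices, row-major order, shape (n, 2)."""
        return np.argwhere(self.valid_mask)

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def subset(self, names: Sequence[str]) -> "EnvStack":
        """New stack restricted to ``names`` (in the given order)."""
        idx = [self.layer_names.index(n) for n in names]
        return EnvStack(
            layer_names=list(names),
            values=self.values[idx],
            cell_size_km=self.cell_size_km,
            nodata_mask=self.nodata_mask.copy(),
        )

    def cell_centers_km(self, cells: np.ndarray) -> np.ndarray:
        """Planar (x, y) center coordinates in km for ``(row, col)`` cells.

        Row 0 sits at the north edge, so y decreases with increasing row.
        """
        cells = np.asarray(cells)
        nrows = self.shape[0]
        x = (cells[:, 1] + 0.5) * self.cell_size_km
        y = (nrows - cells[:, 0] - 0.5) * self.cell_size_km
        return np.column_stack([x, y])


@dataclass
class FeatureTable:
    """Model-ready table: one row per sampled cell.

    ``features`` columns follow the stack's retained-layer order; ``labels``
    are 1 for presences and 0 for pseudo-absences; ``cells`` holds the
    originating ``(row, col)`` index of each row.
    """

    features: pd.DataFrame
    labels: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.cells = np.asarray(self.cells, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be in {0, 1}")
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.cells):
            raise ValueError("features, labels and cells must align row-wise")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def variable_names(self) -> list[str]:
        return list(self.features.columns)

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            cells=self.cells[idx],
        )


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------

def pearson_matrix(stack: EnvStack) -> pd.DataFrame:
    """Pairwise Pearson correlations between layers over valid cells.

    Raises
    ------
    ValueError
        If the stack has fewer than two layers or any layer is constant
        over valid cells (the offending layer is named).
    """
    if stack.n_layers < 2:
        raise ValueError("pearson_matrix requires at least two layers")
    flat = stack.values[:, stack.valid_mask]
    variances = flat.var(axis=1)
    for name, v in zip(stack.layer_names, variances):
        if v <= 0:
            raise ValueError(f"layer '{name}' is constant over valid cells")
    r = np.corrcoef(flat)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=stack.layer_names, columns=stack.layer_names)


def collinearity_filter(stack: EnvStack, cutoff: float = 0.7) -> list[str]:
    """Retained layer names after the pairwise-collinearity screen.

    Pairs with ``|r| >= cutoff`` are visited in descending ``|r|``; from each
    offending pair the member with the larger mean absolute correlation to
    all other currently retained layers is dropped (the "least correlated
    to others" survives).  Ties at every stage are broken by layer-name
    order, making the result deterministic.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    corr = pearson_matrix(stack).abs()
    retained = list(stack.layer_names)
    while True:
        sub = corr.loc[retained, retained]
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.values.max() if len(retained) > 1 else 0.0
        if worst < cutoff:
            break
        # the offending pair with the highest |r|; ties -> name order
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sorted((retained[i], retained[j]))
        others_a = [n for n in retained if n != a]
        others_b = [n for n in retained if n != b]
        mean_a = corr.loc[a, others_a].mean()
        mean_b = corr.loc[b, others_b].mean()
        drop = a if mean_a > mean_b else b if mean_b > mean_a else max(a, b)
        retained.remove(drop)
        logger.debug("collinearity filter dropped %s (mean |r| %.3f vs %.3f)",
                     drop, mean_a, mean_b)
    return retained


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    stack: EnvStack,
    presence_cells: Iterable[tuple[int, int]],
    absence_cells: Iterable[tuple[int, int]],
) -> FeatureTable:
    """Assemble the model input table for presence and pseudo-absence cells.

    Presence rows come first (label 1), then absences (label 0); column
    order follows the stack's layer order.
    """
    pres = np.asarray(list(presence_cells), dtype=int).reshape(-1, 2)
    abs_ = np.asarray(list(absence_cells), dtype=int).reshape(-1, 2)
    if len(pres) == 0:
        raise ValueError("at least one presence cell is required")
    if len(abs_) == 0:
        raise ValueError("at least one pseudo-absence cell is required")
    pres_set = {tuple(c) for c in pres}
    overlap = pres_set & {tuple(c) for c in abs_}
    if overlap:
        raise ValueError(f"presence and absence cells overlap: {sorted(overlap)}")

    cells = np.vstack([pres, abs_])
    rows, cols = cells[:, 0], cells[:, 1]
    nr, nc = stack.shape
    out_of_bounds = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
    if out_of_bounds.any():
        bad = [(int(r), int(c)) for r, c in cells[out_of_bounds]]
        raise ValueError(f"cells outside the grid: {bad}")
    on_nodata = stack.nodata_mask[rows, cols]
    if on_nodata.any():
        bad = [(int(r), int(c)) for r, c in cells[on_nodata]]
        raise ValueError(f"cells on nodata: {bad}")

    data = {name: stack.values[k, rows, cols]
            for k, name in enumerate(stack.layer_names)}
    labels = np.concatenate([np.ones(len(pres), dtype=int),
                             np.zeros(len(abs_), dtype=int)])
    return FeatureTable(features=pd.DataFrame(data), labels=labels, cells=cells)


def features_for_all_cells(stack: EnvStack) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table over every valid cell (for whole-map prediction)."""
    cells = stack.valid_cells()
    data = {name: stack.values[k, cells[:, 0], cells[:, 1]]
            for k, name in enumerate(stack.layer_names)}
    return pd.DataFrame(data), cells


# ---------------------------------------------------------------------------
# File I/O: ESRI ASCII grids and occurrence CSVs
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray,
                     cell_size_km: float = 1.0,
                     nodata_mask: np.ndarray | None = None) -> None:
    """Write one 2-D array as an ESRI ASCII grid (row 0 = north edge)."""
    array = np.asarray(array, dtype=float)
    out = array.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = ASCII_NODATA
    out = np.where(np.isnan(out), ASCII_NODATA, out)
    nrows, ncols = out.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cell_size_km}\n"
        f"NODATA_value {ASCII_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, cellsize, nodata_mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:], dtype=float)
    arr = arr.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", ASCII_NODATA)
    mask = arr == nodata
    arr = np.where(mask, np.nan, arr)
    return arr, header.get("cellsize", 1.0), mask


def write_env_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write each layer as ``<directory>/<layer_name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, name in enumerate(stack.layer_names):
        p = directory / f"{name}.asc"
        write_ascii_grid(p, stack.values[k], stack.cell_size_km,
                         stack.nodata_mask)
        paths.append(p)
    return paths


def read_env_stack(paths: Sequence[str | Path],
                   layer_names: Sequence[str] | None = None) -> EnvStack:
    """Assemble an EnvStack from single-layer ASCII grids.

    Layer names default to the file stems; the union of per-layer nodata
    cells becomes the shared mask.
    """
    paths = [Path(p) for p in paths]
    if layer_names is None:
        layer_names = [p.stem for p in paths]
    arrays, masks, cellsizes = [], [], []
    for p in paths:
        arr, cs, mask = read_ascii_grid(p)
        arrays.append(arr)
        masks.append(mask)
        cellsizes.append(cs)
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("all layers must share one grid shape")
    if len(set(cellsizes)) != 1:
        raise ValueError("all layers must share one cell size")
    mask = np.any(masks, axis=0)
    values = np.stack([np.where(mask, 0.0, a) for a in arrays])
    return EnvStack(layer_names=list(layer_names), values=values,
                    cell_size_km=cellsizes[0], nodata_mask=mask)


def occurrences_to_cells(df: pd.DataFrame, nrows: int,
                         cell_size_km: float = 1.0) -> pd.DataFrame:
    """Convert (species_id, x, y) coordinates to grid cells.

    Columns x, y are planar km with the origin at the grid's south-west
    corner; cells are found by floor division by the cell size and rows
    flipped so row 0 is the north edge.
    """
    required = {"species_id", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    col = np.floor(df["x"].to_numpy() / cell_size_km).astype(int)
    row = nrows - 1 - np.floor(df["y"].to_numpy() / cell_size_km).astype(int)
    return pd.DataFrame({"species_id": df["species_id"].to_numpy(),
                         "row": row, "col": col})


def cells_to_occurrences(cells: np.ndarray, species_id: str, nrows: int,
                         cell_size_km: float = 1.0) -> pd.DataFrame:
    """Inverse of :func:`occurrences_to_cells`, using cell centers."""
    cells = np.asarray(cells, dtype=int)
    x = (cells[:, 1] + 0.5) * cell_size_km
    y = (nrows - cells[:, 0] - 0.5) * cell_size_km
    return pd.DataFrame({"species_id": species_id, "x": x, "y": y})
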