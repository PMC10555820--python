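"""Grid containers shared across the pipeline.

Grids are plain row-major 2-D arrays of shape ``(nrows, ncols)``. Cells are
indexed ``cell = row * ncols + col``; cell centers sit at ``(col + 0.5,
row + 0.5)`` in grid coordinates. Synthetic worlds use unit cells; a real-data
grid resolution (e.g. 5 km) is a configuration of the ingestion path, not
hard-coded anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def cell_index(row: np.ndarray, col: np.ndarray, ncols: int) -> np.ndarray:
    return np.asarray(row) * ncols + np.asarray(col)


def cell_rowcol(cell: np.ndarray, ncols: int) -> tuple[np.ndarray, np.ndarray]:
    cell = np.asarray(cell)
    return cell // ncols, cell % ncols


def cell_centers(grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """x, y coordinates of every cell center, in cell-index order."""
    nrows, ncols = grid_shape
    rows, cols = np.divmod(np.arange(nrows * ncols), ncols)
    return cols + 0.5, rows + 0.5


@dataclass
class EnvLayerStack:
    """Named environmental raster layers on a common grid.

    ``layers`` has shape ``(n_layers, nrows, ncols)``; NaN marks missing
    cells. All layers share the grid geometry by construction.
    """

    layers: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be (n_layers, nrows, ncols)")
        if len(self.names) != self.layers.shape[0]:
            raise ValueError("one name per layer required")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.layers.shape[1], self.layers.shape[2]

    @property
    def n_cells(self) -> int:
        return self.layers.shape[1] * self.layers.shape[2]

    def flat(self) -> np.ndarray:
        """Layers as (n_layers, n_cells)."""
        return self.layers.reshape(self.layers.shape[0], -1)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.names.index(name)]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, lay in zip(self.names, self.layers):
            np.savetxt(outdir / f"{name}.csv", lay, delimiter=",", fmt="%.10g")
        meta = {"names": self.names, "grid_shape": list(self.grid_shape)}
        (outdir / "layers.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, indir: str | Path) -> "EnvLayerStack":
        indir = Path(indir)
        meta = json.loads((indir / "layers.json").read_text())
        arrs = [
            np.loadtxt(indir / f"{n}.csv", delimiter=",", ndmin=2)
            for n in meta["names"]
        ]
        return cls(np.stack(arrs), list(meta["names"]))


@dataclass
class AssemblageGrid:
    """Per-pixel assemblage metrics (mean/min/variance/count layers)."""

    grid_shape: tuple[int, int]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, layer: np.ndarray) -> None:
        layer = np.asarray(layer, dtype=float)
        if layer.shape != tuple(self.grid_shape):
            raise ValueError(f"layer {name!r} does not match grid {self.grid_shape}")
        self.layers[name] = layer

    def flat_table(self):
        """Metrics as a (n_cells, n_layers) pandas DataFrame (NaN = undefined)."""
        import pandas as pd

        return pd.DataFrame(
            {k: v.ravel() for k, v in self.layers.items()},
            index=np.arange(self.grid_shape[0] * self.grid_shape[1]),
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, lay in self.layers.items():
            np.savetxt(outdir / f"{name}.csv", lay, delimiter=",", fmt="%.10g")
        meta = {"names": self.names, "grid_shape": list(self.grid_shape)}
        (outdir / "metrics.json").write_text(json.dumps(meta, indent=1))
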