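"""Gridded win-win prioritization of croplands for bird conservation.

A cell is a priority when it scores in the top tercile of *both* a crop
"benefit" index (the share of woody crops in total crop production --
woody crops being the ones birds tend to benefit) and a bird conservation
index (here, the product of min-max standardized threatened-species
richness and total species richness).  The bivariate classification
crosses the terciles of the two indices into a 3x3 legend (codes 1-9);
class 9 (top/top) is the priority mask.

Grids are plain 2-D arrays with a nodata mask and cell-center
registration (row 0 = northernmost row).  Co-analyzed layers must share
shape, registration and mask conventions; nothing is resampled silently.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass
class GridLayer:
    """A co-registered 2-D non-negative raster with a nodata mask.

    ``mask`` is True where the cell is missing.  ``origin`` is the (x, y)
    of the center of the top-left cell; rows run north to south.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.mask = self.mask | ~np.isfinite(self.values)
        if np.any(self.values[~self.mask] < 0):
            raise ValueError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_registration(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridLayer":
        return GridLayer(
            values=values,
            mask=self.mask.copy() if mask is None else mask,
            origin=self.origin,
            cellsize=self.cellsize,
        )


@dataclasses.dataclass
class BivariateClassGrid:
    """3x3 bivariate tercile classification and its priority mask."""

    classes: np.ndarray  # codes 1..9, 0 = missing
    priority: np.ndarray  # bool, True where both inputs are top-tercile
    benefit_tercile: np.ndarray
    conservation_tercile: np.ndarray
    origin: tuple[float, float]
    cellsize: float

    def legend(self) -> list[dict]:
        rows = []
        for cons in (1, 2, 3):
            for ben in (1, 2, 3):
                rows.append(
                    {
                        "class": 3 * (cons - 1) + ben,
                        "benefit_tercile": ben,
                        "conservation_tercile": cons,
                        "priority": ben == 3 and cons == 3,
                    }
                )
        return rows


def _check_registration(*layers: GridLayer) -> None:
    first = layers[0]
    for other in layers[1:]:
        if not first.same_registration(other):
            raise ValueError(
                "grid layers are not co-registered (shape/origin/cellsize differ); "
                "resample explicitly before combining"
            )


def benefit_index(woody: GridLayer, total: GridLayer) -> GridLayer:
    """Cellwise share of woody-crop production in total crop production.

    Cells with zero total production become missing (oceans and no-crop
    land must not enter the tercile computation as zero benefit).
    """
    _check_registration(woody, total)
    mask = woody.mask | total.mask
    both = ~mask
    bad = both & (woody.values > total.values)
    if np.any(bad):
        cells = list(zip(*np.nonzero(bad)))
        raise ValueError(
            f"woody production exceeds total production at cells {cells[:10]}"
            + (" ..." if len(cells) > 10 else "")
        )
    out = np.full(woody.shape, np.nan)
    nonzero = both & (total.values > 0)
    out[nonzero] = woody.values[nonzero] / total.values[nonzero]
    return woody.with_values(out, mask=~nonzero)


def standardize_minmax(layer: GridLayer) -> GridLayer:
    """(x - min)/(max - min) over non-missing cells, into [0, 1].

    A constant layer maps to all zeros (with a warning) so downstream
    products stay defined.
    """
    vals = layer.valid()
    if vals.size == 0:
        raise ValueError("layer has no non-missing cells")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(layer.shape, np.nan)
    if hi == lo:
        warnings.warn("constant layer: min-max standardization maps to all 0", stacklevel=2)
        out[~layer.mask] = 0.0
    else:
        out[~layer.mask] = (layer.values[~layer.mask] - lo) / (hi - lo)
    return layer.with_values(out)


def integrative_index(threatened_richness: GridLayer, total_richness: GridLayer) -> GridLayer:
    """Product of the min-max standardized richness layers (symmetric)."""
    _check_registration(threatened_richness, total_richness)
    a = standardize_minmax(threatened_richness)
    b = standardize_minmax(total_richness)
    mask = a.mask | b.mask
    out = np.full(a.shape, np.nan)
    out[~mask] = a.values[~mask] * b.values[~mask]
    return GridLayer(out, mask=mask, origin=a.origin, cellsize=a.cellsize)


def tercile_classify(layer: GridLayer) -> np.ndarray:
    """Tercile codes {1, 2, 3} over non-missing cells (0 = missing).

    Cuts at the 33.33% / 66.67% linear-interpolation quantiles; ties at a
    boundary go to the lower tercile; code 3 is the top tercile.
    """
    vals = layer.valid()
    if vals.size < 3:
        raise ValueError("tercile classification needs at least 3 non-missing cells")
    q1, q2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    if q1 == q2 and vals.min() == vals.max():
        warnings.warn("constant layer: all cells assigned to tercile 1", stacklevel=2)
    codes = np.zeros(layer.shape, dtype=int)
    v = layer.values
    ok = ~layer.mask
    codes[ok] = np.where(v[ok] <= q1, 1, np.where(v[ok] <= q2, 2, 3))
    return codes


def priority_mask(benefit: GridLayer, conservation: GridLayer) -> BivariateClassGrid:
    """Bivariate tercile classification; priority = top tercile of both.

    Class code = 3*(conservation tercile - 1) + benefit tercile; a cell
    missing in either input is unclassified (code 0).
    """
    _check_registration(benefit, conservation)
    ben = tercile_classify(benefit)
    con = tercile_classify(conservation)
    both = (ben > 0) & (con > 0)
    classes = np.zeros(benefit.shape, dtype=int)
    classes[both] = 3 * (con[both] - 1) + ben[both]
    ben_out = np.where(both, ben, 0)
    con_out = np.where(both, con, 0)
    return BivariateClassGrid(
        classes=classes,
        priority=classes == 9,
        benefit_tercile=ben_out,
        conservation_tercile=con_out,
        origin=benefit.origin,
        cellsize=benefit.cellsize,
    )
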