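"""Per-pixel moving-window landscape pattern indices.

For a categorical raster (here: the 11-category land-cover change map) and
odd window sizes w in {3, 5, 7}, four indices are assigned to each window's
central pixel:

HET   number of distinct classes among the window's valid cells; 1 means
      the center sits in a homogeneous block.
HOM   number of valid cells sharing the center pixel's class (center
      included).
DMG   dominance: ln(K) - H, where H is the Shannon entropy of the class
      proportions P_k over valid window cells and K is the global number
      of categories present in the whole map, so the ceiling is the same
      for every pixel.  Clamped at 0 against floating-point undershoot.
CON   contagion: 2 ln(N) - ent, where N is the number of classes present
      in the window and ent is the entropy of the rook (4-neighbour)
      adjacency distribution, adjacencies counted in both orders and
      only between cell pairs fully inside the window.  A one-class
      window gives 0 by literal application of the formula.

Windows slide one pixel at a time; border pixels whose w x w window falls
outside the raster get nodata, so no mixed-support values enter the
samples.  Nodata cells inside a window are dropped from the proportion and
adjacency tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .geodata import CategoricalRaster, ContinuousRaster

__all__ = [
    "MetricStack",
    "METRIC_NAMES",
    "window_het",
    "window_hom",
    "window_dmg",
    "window_con",
    "focal_metrics",
]

METRIC_NAMES = ("HET", "HOM", "DMG", "CON")


# ---------------------------------------------------------------------------
# Single-window forms (operate on a flat multiset of class codes)


def _valid_cells(cells, nodata: int) -> np.ndarray:
    arr = np.asarray(cells).ravel()
    return arr[arr != nodata]


def window_het(cells, nodata: int = -1) -> float:
    """Number of distinct valid classes in the window; NaN if all nodata."""
    v = _valid_cells(cells, nodata)
    if v.size == 0:
        return float("nan")
    return float(np.unique(v).size)


def window_hom(cells, center_class, nodata: int = -1) -> float:
    """Count of valid cells equal to the center class; NaN if center is nodata."""
    if center_class == nodata:
        return float("nan")
    v = _valid_cells(cells, nodata)
    return float((v == center_class).sum())


def window_dmg(cells, k_global: int, nodata: int = -1) -> float:
    """Dominance ln(K) - Shannon entropy of valid-cell class proportions."""
    if k_global < 1:
        raise ValueError("global category count K must be >= 1")
    v = _valid_cells(cells, nodata)
    if v.size == 0:
        return float("nan")
    _, counts = np.unique(v, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return max(np.log(k_global) - h, 0.0)


def window_con(cells, nodata: int = -1) -> float:
    """Contagion 2 ln(N) - adjacency entropy over a 2-D window.

    ``cells`` must be a 2-D array (the window itself) since adjacency needs
    the spatial arrangement; 1x1 windows carry no interior adjacency and
    are rejected.
    """
    win = np.asarray(cells)
    if win.ndim != 2:
        raise ValueError("window_con needs the 2-D window, not a flat multiset")
    if win.shape[0] < 2 and win.shape[1] < 2:
        raise ValueError("window has no interior adjacency")
    v = win[win != nodata]
    if v.size == 0:
        return float("nan")
    n_classes = np.unique(v).size
    pairs: dict[tuple[int, int], int] = {}

    def _tally(a, b):
        for x, y in zip(a.ravel().tolist(), b.ravel().tolist()):
            if x == nodata or y == nodata:
                continue
            key = (x, y) if x <= y else (y, x)
            pairs[key] = pairs.get(key, 0) + 1

    _tally(win[:, :-1], win[:, 1:])
    _tally(win[:-1, :], win[1:, :])
    total_unordered = sum(pairs.values())
    if total_unordered == 0:
        return float("nan")
    ent = 0.0
    for (i, j), cnt in pairs.items():
        if i == j:
            p = cnt / total_unordered  # both orders collapse onto the diagonal
            ent -= p * np.log(p)
        else:
            p = cnt / (2 * total_unordered)  # split across (i,j) and (j,i)
            ent -= 2 * p * np.log(p)
    return float(2.0 * np.log(n_classes) - ent)


# ---------------------------------------------------------------------------
# Focal (whole-raster) computation


@dataclass
class MetricStack:
    """HET/HOM/DMG/CON layers per window size, aligned with the source map."""

    source: CategoricalRaster
    window_sizes: tuple[int, ...]
    k_global: int
    layers: dict[str, ContinuousRaster] = field(default_factory=dict)

    def layer(self, name: str) -> ContinuousRaster:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return [f"{m}{w}" for w in self.window_sizes for m in METRIC_NAMES]

    def values_at(self, rows, cols, names=None) -> dict[str, np.ndarray]:
        names = list(names) if names is not None else self.names
        return {n: self.layers[n].values[rows, cols] for n in names}


def _winsum(arr: np.ndarray, wy: int, wx: int) -> np.ndarray:
    """Sliding-window sums of an integer array over wy x wx windows."""
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(arr, (wy, wx)).sum(axis=(-2, -1))


def _focal_one(raster: CategoricalRaster, w: int, k_global: int):
    codes = raster.codes
    nodata = raster.nodata
    n_rows, n_cols = codes.shape
    if w > n_rows or w > n_cols:
        raise ValueError(f"window size {w} exceeds raster dimensions {codes.shape}")
    classes = np.unique(codes[codes != nodata])
    m = w // 2

    # per-class membership and window counts (integral over w x w)
    member = np.stack([(codes == c).astype(np.int64) for c in classes])
    counts = np.stack([_winsum(member[i], w, w) for i in range(len(classes))])
    valid_counts = counts.sum(axis=0)

    het = (counts > 0).sum(axis=0).astype(float)
    het[valid_counts == 0] = np.nan

    # HOM: count of the center's class; nodata centers -> NaN
    centers = codes[m : n_rows - m, m : n_cols - m]
    hom = np.full(centers.shape, np.nan)
    for i, c in enumerate(classes):
        mask = centers == c
        hom[mask] = counts[i][mask]

    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / valid_counts
        plogp = np.where(counts > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=0)
    dmg = np.maximum(np.log(k_global) - entropy, 0.0)
    dmg[valid_counts == 0] = np.nan

    # CON: rook adjacency tallies via sliding sums over the edge arrays
    h_l, h_r = codes[:, :-1], codes[:, 1:]
    v_t, v_b = codes[:-1, :], codes[1:, :]
    ent_adj = np.zeros_like(het)
    total_edges = np.zeros_like(het)
    pair_counts = {}
    for a, b in combinations_with_replacement(classes.tolist(), 2):
        h_mask = ((h_l == a) & (h_r == b)) | ((h_l == b) & (h_r == a))
        v_mask = ((v_t == a) & (v_b == b)) | ((v_t == b) & (v_b == a))
        cnt = _winsum(h_mask.astype(np.int64), w, w - 1) + _winsum(
            v_mask.astype(np.int64), w - 1, w
        )
        pair_counts[(a, b)] = cnt
        total_edges += cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        for (a, b), cnt in pair_counts.items():
            if a == b:
                p = cnt / total_edges
                ent_adj -= np.where(cnt > 0, p * np.log(p), 0.0)
            else:
                p = cnt / (2.0 * total_edges)
                ent_adj -= np.where(cnt > 0, 2.0 * p * np.log(p), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        con = 2.0 * np.log(het) - ent_adj
    con[(valid_counts == 0) | (total_edges == 0)] = np.nan

    def _embed(interior: np.ndarray) -> np.ndarray:
        out = np.full((n_rows, n_cols), np.nan)
        out[m : n_rows - m, m : n_cols - m] = interior
        return out

    return {
        f"HET{w}": _embed(het),
        f"HOM{w}": _embed(hom),
        f"DMG{w}": _embed(dmg),
        f"CON{w}": _embed(con),
    }


def focal_metrics(
    raster: CategoricalRaster,
    window_sizes=(3, 5, 7),
    k_global: int | None = None,
) -> MetricStack:
    """Compute all four indices at every window size over a category raster.

    ``k_global`` defaults to the number of categories present in the map
    (the dominance ceiling shared by all pixels).
    """
    sizes = tuple(int(w) for w in window_sizes)
    for w in sizes:
        if w < 3 or w % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {w}")
    if k_global is None:
        k_global = int(np.unique(raster.codes[raster.valid_mask]).size)
    stack = MetricStack(raster, sizes, k_global)
    for w in sizes:
        for name, arr in _focal_one(raster, w, k_global).items():
            stack.layers[name] = ContinuousRaster(raster.grid, arr)
    return stack
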