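"""Extraction of co-expressed gene modules from the SOM landscape.

Modules are connected regions of the metagene grid (8-neighborhood on the
square grid) together with the genes assigned to their units. Six selection
modes are provided: single-spot overexpression, group overexpression,
underexpression, k-means on metagene vectors, correlation clustering of
grid-adjacent units, and distance-map (U-matrix) segmentation. Labels A, B,
... are assigned by decreasing unit count (then top-left-most unit) so that
the labeling is deterministic; they are analysis-specific, not universal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .som import Portrait, SomPortrayal
from .types import DataError

_EIGHT = np.ones((3, 3), dtype=int)

METHODS = (
    "single_spot_overexpression",
    "group_overexpression",
    "underexpression",
    "kmeans",
    "correlation_cluster",
    "dmap",
)


@dataclass
class Module:
    label: str
    units: frozenset  # of (row, col)
    gene_ids: list[str]
    method: str


@dataclass
class ModuleSet:
    modules: list[Module] = field(default_factory=list)
    method: str = "group_overexpression"
    grid_shape: tuple[int, int] = (0, 0)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def get(self, label: str) -> Module:
        for m in self.modules:
            if m.label == label:
                return m
        raise DataError(f"unknown module label {label!r}")

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.modules]


def _label_name(i: int) -> str:
    # A..Z, then AA, AB, ...
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def _components_to_modules(
    comp_units: list[list[tuple[int, int]]],
    model: SomPortrayal,
    method: str,
) -> list[Module]:
    """Sort components by decreasing size then top-left-most unit; attach genes."""
    unit_genes = model.unit_genes()
    ordered = sorted(comp_units, key=lambda units: (-len(units), min(units)))
    modules = []
    for i, units in enumerate(ordered):
        genes = [g for u in sorted(units) for g in unit_genes.get(u, [])]
        modules.append(Module(_label_name(i), frozenset(units), genes, method))
    return modules


def _connected_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    return [
        [tuple(int(x) for x in rc) for rc in np.argwhere(labeled == k)]
        for k in range(1, n + 1)
    ]


def overexpression_modules(
    model: SomPortrayal,
    portraits: list[Portrait],
    threshold_quantile: float | None = None,
    min_units: int = 4,
    underexpression: bool = False,
    peak_fraction: float = 0.5,
    method: str | None = None,
) -> ModuleSet:
    """Modules from high-value (or low-value) regions of one or more portraits.

    For each portrait, units above a per-portrait threshold are marked (the
    sign is flipped first for underexpression); marked masks are unioned
    across portraits, and connected components with at least ``min_units``
    units become modules.

    The default threshold is ``peak_fraction`` (half by default) of the
    portrait's maximum — a full-width-at-half-maximum spot criterion that
    adapts to the activation spot's own extent, so the marked region tracks
    the co-expressed gene blob rather than a fixed share of the grid.
    Passing ``threshold_quantile`` switches to a fixed value-quantile cut
    (e.g. 0.9 marks the top decile of units of each portrait); raising it
    never enlarges any module.
    """
    if not portraits:
        raise DataError("no portraits supplied")
    if threshold_quantile is not None and not (0 < threshold_quantile < 1):
        raise DataError("threshold_quantile must be in (0, 1)")
    if threshold_quantile is None and not (0 < peak_fraction < 1):
        raise DataError("peak_fraction must be in (0, 1)")
    shape = (model.grid_rows, model.grid_cols)
    mask = np.zeros(shape, dtype=bool)
    for p in portraits:
        if p.values.shape != shape:
            raise DataError("portrait grid does not match the model grid")
        v = -p.values if underexpression else p.values
        if threshold_quantile is not None:
            cut = np.quantile(v, threshold_quantile)
        else:
            vmax = v.max()
            if vmax <= 0:  # no overexpressed unit in this portrait
                continue
            cut = peak_fraction * vmax
        mask |= v > cut
    if method is None:
        method = "underexpression" if underexpression else (
            "single_spot_overexpression"
            if all(p.kind == "single_spot" for p in portraits)
            else "group_overexpression"
        )
    comps = [c for c in _connected_components(mask) if len(c) >= min_units]
    return ModuleSet(_components_to_modules(comps, model, method), method, shape)


def single_spot_overexpression_modules(model: SomPortrayal, barcodes=None, **kw) -> ModuleSet:
    barcodes = barcodes or model.spot_barcodes_
    portraits = [model.spot_portrait(b) for b in barcodes]
    return overexpression_modules(model, portraits, method="single_spot_overexpression", **kw)


def kmeans_segmentation(model: SomPortrayal, k: int, seed: int = 0) -> ModuleSet:
    """Partition the grid by k-means on the metagene weight vectors."""
    model._check_fitted()
    if not (2 <= k <= model.n_units):
        raise DataError(f"k={k} out of range [2, {model.n_units}]")
    flat = model.weights_.reshape(model.n_units, -1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(flat)
    comps = []
    for lab in range(k):
        units = [
            (int(i // model.grid_cols), int(i % model.grid_cols))
            for i in np.flatnonzero(km.labels_ == lab)
        ]
        if units:
            comps.append(units)
    return ModuleSet(
        _components_to_modules(comps, model, "kmeans"), "kmeans",
        (model.grid_rows, model.grid_cols),
    )


def _grid_neighbors(r: int, c: int, shape: tuple[int, int]):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                yield rr, cc


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 1.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def correlation_cluster_segmentation(model: SomPortrayal, threshold: float) -> ModuleSet:
    """Union grid-adjacent units whose weight vectors correlate above threshold."""
    model._check_fitted()
    if not (-1 < threshold < 1):
        raise DataError("threshold must be in (-1, 1)")
    shape = (model.grid_rows, model.grid_cols)
    # union-find over units linked by (adjacency AND correlation >= threshold)
    parent = {u: u for u in np.ndindex(shape)}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for r, c in np.ndindex(shape):
        for rr, cc in _grid_neighbors(r, c, shape):
            if (rr, cc) < (r, c):
                continue
            if _pearson(model.weights_[r, c], model.weights_[rr, cc]) >= threshold:
                ra, rb = find((r, c)), find((rr, cc))
                if ra != rb:
                    parent[rb] = ra
    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for u in np.ndindex(shape):
        groups.setdefault(find(u), []).append(u)
    return ModuleSet(
        _components_to_modules(list(groups.values()), model, "correlation_cluster"),
        "correlation_cluster", shape,
    )


def distance_map(model: SomPortrayal) -> np.ndarray:
    """U-matrix: per unit, mean Euclidean distance to its grid neighbors' weights."""
    model._check_fitted()
    shape = (model.grid_rows, model.grid_cols)
    dmap = np.zeros(shape)
    for r, c in np.ndindex(shape):
        ds = [
            np.linalg.norm(model.weights_[r, c] - model.weights_[rr, cc])
            for rr, cc in _grid_neighbors(r, c, shape)
        ]
        dmap[r, c] = np.mean(ds)
    return dmap


def dmap_segmentation(model: SomPortrayal, boundary_quantile: float = 0.9) -> ModuleSet:
    """Split the grid along high-distance ridges of the U-matrix."""
    if not (0 < boundary_quantile < 1):
        raise DataError("boundary_quantile must be in (0, 1)")
    dmap = distance_map(model)
    cut = np.quantile(dmap, boundary_quantile)
    interior = dmap <= cut
    comps = _connected_components(interior)
    return ModuleSet(
        _components_to_modules(comps, model, "dmap"), "dmap",
        (model.grid_rows, model.grid_cols),
    )


def module_spatial_score(model: SomPortrayal, module_set: ModuleSet, label: str) -> pd.Series:
    """Per-spot mean of the module's metagene components.

    Equivalently: the mean of the module's unit values in each spot's
    portrait — the value used to color the tissue image by module activity.
    """
    model._check_fitted()
    module = module_set.get(label)
    units = sorted(module.units)
    vals = np.stack([model.weights_[r, c] for r, c in units])  # (n_units, n_spots)
    return pd.Series(vals.mean(axis=0), index=model.spot_barcodes_, name=f"module_{label}")
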