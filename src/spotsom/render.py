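"""Rasterization of portraits, spatial value maps, and RLI call maps.

Conventions follow the browser-style colorings: portraits on a diverging
red (over) to blue (under) scale centered at zero; spatial expression maps
on a sequential brown (high) to blue (low) scale; receptor-ligand calls in
apricot (coexpressed) / blue (receptor only) / green (ligand only), with
color saturation scaling by expression level. All functions are pure:
identical inputs produce byte-identical uint8 RGB arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image, ImageDraw

from .som import Portrait
from .types import DataError, SpatialLayout

# single palette constant: the named colors of the RLI convention
RLI_PALETTE = {
    "coexpressed": (237, 145, 33),   # apricot
    "receptor_only": (43, 87, 184),  # blue
    "ligand_only": (46, 139, 87),    # green
    "none": (255, 255, 255),
}

_DIVERGING = LinearSegmentedColormap.from_list(
    "blue_white_red", ["#2166ac", "#f7f7f7", "#b2182b"]
)
_SEQUENTIAL = LinearSegmentedColormap.from_list(
    "blue_to_brown", ["#2166ac", "#f6e8c3", "#8c510a"]
)


@dataclass
class ColorSpec:
    mode: str = "diverging_red_blue"
    normalization: str = "symmetric_about_zero"
    saturation_quantile: float = 0.99
    vmin: float | None = None  # used when normalization == "global"
    vmax: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("diverging_red_blue", "sequential_brown_blue", "rli_triple",
                             "categorical"):
            raise DataError(f"unknown color mode {self.mode!r}")
        if self.normalization not in ("per_image", "global", "symmetric_about_zero"):
            raise DataError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "symmetric_about_zero" and self.mode != "diverging_red_blue":
            raise DataError("symmetric_about_zero requires the diverging mode")
        if not (0.5 < self.saturation_quantile <= 1):
            raise DataError("saturation_quantile must be in (0.5, 1]")


def _normalize(values: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Map values to [0, 1] per the color settings; midpoint for flat input."""
    v = np.asarray(values, dtype=float)
    if spec.normalization == "symmetric_about_zero":
        vmax = float(np.quantile(np.abs(v), spec.saturation_quantile))
        if vmax == 0:
            return np.full(v.shape, 0.5)
        return np.clip(v / vmax, -1.0, 1.0) / 2.0 + 0.5
    if spec.normalization == "global":
        if spec.vmin is None or spec.vmax is None:
            raise DataError("global normalization requires vmin and vmax")
        vmin, vmax = float(spec.vmin), float(spec.vmax)
    else:  # per_image
        vmin = float(np.quantile(v, 1.0 - spec.saturation_quantile))
        vmax = float(np.quantile(v, spec.saturation_quantile))
    if vmax <= vmin:
        return np.full(v.shape, 0.5)
    return np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)


def _apply_cmap(unit: np.ndarray, spec: ColorSpec) -> np.ndarray:
    cmap = _DIVERGING if spec.mode == "diverging_red_blue" else _SEQUENTIAL
    rgba = cmap(unit)
    return (np.asarray(rgba)[..., :3] * 255).round().astype(np.uint8)


def render_portrait(
    portrait: Portrait, spec: ColorSpec | None = None, cell_size: int = 8
) -> np.ndarray:
    """Raster (H, W, 3) uint8 image of a portrait, one cell per metagene."""
    spec = spec or ColorSpec()
    if not np.isfinite(portrait.values).all():
        raise DataError("portrait contains NaN or infinite values")
    unit = _normalize(portrait.values, spec)
    rgb = _apply_cmap(unit, spec)
    return np.repeat(np.repeat(rgb, cell_size, axis=0), cell_size, axis=1)


def _canvas_and_positions(layout: SpatialLayout, barcodes, scale_factor, radius):
    t = layout.table
    xs = t.loc[barcodes, "pixel_x"].to_numpy(dtype=float) * scale_factor
    ys = t.loc[barcodes, "pixel_y"].to_numpy(dtype=float) * scale_factor
    pad = radius + 2
    x0, y0 = xs.min() - pad, ys.min() - pad
    width = int(np.ceil(xs.max() - x0 + pad + 1))
    height = int(np.ceil(ys.max() - y0 + pad + 1))
    return (width, height), xs - x0, ys - y0


def render_spatial(
    values,
    layout: SpatialLayout,
    spec: ColorSpec | None = None,
    scale_factor: float = 1.0,
    spot_radius: float = 4.0,
) -> np.ndarray:
    """One colored disk per in-tissue spot at scaled pixel coordinates.

    ``values`` is a mapping/Series barcode -> value covering every in-tissue
    barcode of the layout; out-of-tissue spots are never drawn.
    """
    spec = spec or ColorSpec(mode="sequential_brown_blue", normalization="per_image")
    barcodes = layout.in_tissue_barcodes
    missing = [b for b in barcodes if b not in values]
    if missing:
        raise DataError(f"values missing for in-tissue barcodes {missing[:5]}")
    for b in values.keys() if hasattr(values, "keys") else []:
        if b not in layout.table.index:
            raise DataError(f"barcode {b!r} has no coordinates in the layout")
    vals = np.array([float(values[b]) for b in barcodes])
    unit = _normalize(vals, spec)
    colors = _apply_cmap(unit, spec)
    (width, height), xs, ys = _canvas_and_positions(layout, barcodes, scale_factor, spot_radius)
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    for (x, y, rgb) in zip(xs, ys, colors):
        draw.ellipse(
            [x - spot_radius, y - spot_radius, x + spot_radius, y + spot_radius],
            fill=tuple(int(c) for c in rgb),
        )
    return np.asarray(img)


def render_rli(
    calls,
    layout: SpatialLayout,
    scale_factor: float = 1.0,
    spot_radius: float = 4.0,
) -> np.ndarray:
    """Apricot/blue/green disks for RLI calls, saturation-blended to white.

    ``calls`` is the DataFrame from :func:`spotsom.rli.classify_rli` or
    :func:`spotsom.rli.pathway_rli_map` (columns ``state``, ``saturation``),
    covering the in-tissue barcodes. Spots in state ``none`` are left
    uncolored.
    """
    barcodes = layout.in_tissue_barcodes
    missing = [b for b in barcodes if b not in calls.index]
    if missing:
        raise DataError(f"calls missing for in-tissue barcodes {missing[:5]}")
    (width, height), xs, ys = _canvas_and_positions(layout, barcodes, scale_factor, spot_radius)
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    white = np.array([255.0, 255.0, 255.0])
    for b, x, y in zip(barcodes, xs, ys):
        state = calls.loc[b, "state"]
        if state not in RLI_PALETTE:
            raise DataError(f"unknown RLI state {state!r}")
        if state == "none":
            continue
        sat = float(np.clip(calls.loc[b, "saturation"], 0.0, 1.0))
        rgb = white * (1.0 - sat) + np.array(RLI_PALETTE[state], dtype=float) * sat
        draw.ellipse(
            [x - spot_radius, y - spot_radius, x + spot_radius, y + spot_radius],
            fill=tuple(int(round(c)) for c in rgb),
        )
    return np.asarray(img)


def save_png(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path, format="PNG")
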