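"""Synthetic Visium-style fixtures with known ground truth.

Generates a hex lattice of spots partitioned into contiguous spatial
domains, with one co-expressed gene module per domain: a module gene's
negative-binomial mean is ``base_mean * fold_change`` inside its home
domain and ``base_mean`` elsewhere; background genes are flat everywhere.
Spot totals are scaled to library sizes drawn log-normally around
``library_size_mean``. Domains are grown by multi-source breadth-first
search from random centers on the hex adjacency graph (a lattice Voronoi
under hex graph distance), which guarantees every domain is connected.

The defaults are the desk-scale study conditions used throughout the test
suite: a 20 x 20 lattice, 4 domains, 50 genes per module, 500 background
genes, fold change 4, and moderately overdispersed counts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DataError, ExpressionMatrix, SpatialLayout, SpotLabels


@dataclass
class SyntheticConfig:
    n_rows: int = 20
    n_cols: int = 20
    n_domains: int = 4
    genes_per_module: int = 50
    n_background_genes: int = 500
    base_mean: float = 2.0
    fold_change: float = 4.0
    dispersion: float = 2.0          # NB size parameter; var = mu + mu^2/dispersion
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.25  # lognormal sigma of library sizes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DataError("lattice dimensions must be positive")
        if self.n_domains < 2 or self.n_domains > self.n_rows * self.n_cols:
            raise DataError("need 2 <= n_domains <= number of spots")
        if self.genes_per_module < 1 and self.n_background_genes < 1:
            raise DataError("config yields zero genes")
        for name in ("base_mean", "fold_change", "dispersion", "library_size_mean"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.fold_change < 1:
            raise DataError("fold_change must be >= 1")


@dataclass
class GroundTruth:
    spot_domain: dict[str, int]
    module_genes: dict[str, list[str]] = field(default_factory=dict)
    module_domain: dict[str, int] = field(default_factory=dict)

    def domain_barcodes(self, domain: int) -> list[str]:
        return [b for b, d in self.spot_domain.items() if d == domain]

    def as_labels(self) -> SpotLabels:
        """Domain assignment as cluster labels (the user-supplied clustering)."""
        return SpotLabels({b: f"domain{d}" for b, d in self.spot_domain.items()}, "cluster")


def _hex_layout(n_rows: int, n_cols: int) -> SpatialLayout:
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            col = 2 * c + (r % 2)  # Visium convention: col parity == row parity
            rows.append(
                {
                    "barcode": f"spot_r{r:02d}c{c:02d}",
                    "in_tissue": True,
                    "array_row": r,
                    "array_col": col,
                    "pixel_x": col * 50.0,
                    "pixel_y": r * 86.6,
                }
            )
    return SpatialLayout(pd.DataFrame(rows).set_index("barcode"))


def _hex_neighbors(r: int, col: int):
    yield r, col - 2
    yield r, col + 2
    for dr in (-1, 1):
        for dc in (-1, 1):
            yield r + dr, col + dc


def _grow_domains(layout: SpatialLayout, n_domains: int, rng: np.random.Generator) -> dict[str, int]:
    """Multi-source BFS from random centers; contiguous by construction."""
    barcodes = layout.barcodes
    coord_of = {
        b: (int(layout.table.loc[b, "array_row"]), int(layout.table.loc[b, "array_col"]))
        for b in barcodes
    }
    by_coord = {v: k for k, v in coord_of.items()}
    centers = rng.choice(len(barcodes), size=n_domains, replace=False)
    assignment: dict[str, int] = {}
    queue: deque[tuple[str, int]] = deque()
    for d, ci in enumerate(centers):
        b = barcodes[int(ci)]
        assignment[b] = d
        queue.append((b, d))
    while queue:
        b, d = queue.popleft()
        r, col = coord_of[b]
        for nb_coord in _hex_neighbors(r, col):
            nb = by_coord.get(nb_coord)
            if nb is not None and nb not in assignment:
                assignment[nb] = d
                queue.append((nb, d))
    return assignment


def generate(config: SyntheticConfig | None = None) -> tuple[ExpressionMatrix, SpatialLayout, GroundTruth]:
    """Draw one synthetic dataset; deterministic for a fixed config seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    layout = _hex_layout(config.n_rows, config.n_cols)
    spot_domain = _grow_domains(layout, config.n_domains, rng)
    barcodes = layout.barcodes
    domain_of = np.array([spot_domain[b] for b in barcodes])

    module_genes: dict[str, list[str]] = {}
    module_domain: dict[str, int] = {}
    gene_ids: list[str] = []
    for d in range(config.n_domains):
        name = f"module{d}"
        genes = [f"MOD{d}_G{i:03d}" for i in range(config.genes_per_module)]
        module_genes[name] = genes
        module_domain[name] = d
        gene_ids.extend(genes)
    gene_ids.extend(f"BG_G{i:03d}" for i in range(config.n_background_genes))

    n_genes, n_spots = len(gene_ids), len(barcodes)
    mean = np.full((n_genes, n_spots), config.base_mean)
    for d in range(config.n_domains):
        rows = slice(d * config.genes_per_module, (d + 1) * config.genes_per_module)
        mean[rows, domain_of == d] *= config.fold_change

    libs = rng.lognormal(
        mean=np.log(config.library_size_mean) - config.library_size_sigma**2 / 2,
        sigma=config.library_size_sigma,
        size=n_spots,
    )
    # scale by the library draw over the *average* expected total, not the
    # spot's own total: per-spot exact scaling would deflate the in/out-domain
    # fold ratio of module genes (their domain gets a larger denominator)
    mu = mean * (libs / mean.sum(axis=0).mean())[None, :]
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    matrix = ExpressionMatrix(gene_ids, barcodes, counts.astype(float), stage="raw_counts")
    return matrix, layout, GroundTruth(spot_domain, module_genes, module_domain)


def write_ground_truth(directory, truth: GroundTruth) -> None:
    """Write the ground truth as plain TSVs next to a fixture directory."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "spot_domains.tsv", "w") as fh:
        fh.write("barcode\tdomain\n")
        for b, d in truth.spot_domain.items():
            fh.write(f"{b}\t{d}\n")
    with open(directory / "module_genes.gmt", "w") as fh:
        for name, genes in truth.module_genes.items():
            fh.write("\t".join([name, f"domain{truth.module_domain[name]}", *genes]) + "\n")
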