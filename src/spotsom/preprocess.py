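"""Raw spot counts -> normalized, log-transformed, gene-centralized values.

The SOM consumes each gene's expression profile across spots after three
deterministic steps:

1. ``filter_genes`` — drop genes detected in fewer than ``min_spots_expressed``
   spots or with zero variance (they destabilize training and carry no
   portrait signal).
2. ``normalize`` — scale every spot column to a common library size
   (median library size by default, or counts-per-10k).
3. ``log_and_centralize`` — ``log(value + pseudocount)`` followed by
   subtraction of each gene's mean across spots. Centralization is per gene,
   across spots: this is what makes portrait values signed over/under-
   expression relative to the gene's own average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DataError, ExpressionMatrix


@dataclass
class PreprocessConfig:
    min_spots_expressed: int = 3
    normalization_target: str = "median_library_size"  # or "counts_per_10k"
    log_base: float = 2.0  # 2 or e
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise DataError("pseudocount must be positive")
        if self.min_spots_expressed < 0:
            raise DataError("min_spots_expressed must be >= 0")
        if self.normalization_target not in ("median_library_size", "counts_per_10k"):
            raise DataError(f"unknown normalization_target {self.normalization_target!r}")


def filter_genes(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Keep genes with count > 0 in >= min_spots_expressed spots and nonzero variance."""
    config = config or PreprocessConfig()
    if matrix.stage != "raw_counts":
        raise DataError(f"filter_genes expects raw_counts, got stage {matrix.stage!r}")
    detected = (matrix.values > 0).sum(axis=1)
    nonconstant = matrix.values.var(axis=1) > 0
    keep = (detected >= config.min_spots_expressed) & nonconstant
    if not keep.any():
        raise DataError("gene filter removed every gene")
    return matrix.subset_genes(keep)


def normalize(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Scale each spot column to the target library size."""
    config = config or PreprocessConfig()
    if matrix.stage != "raw_counts":
        raise DataError(f"normalize expects raw_counts, got stage {matrix.stage!r}")
    totals = matrix.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [matrix.spot_barcodes[j] for j in np.flatnonzero(zero)]
        raise DataError(f"spots with zero total counts: {bad}")
    if config.normalization_target == "median_library_size":
        target = float(np.median(totals))
    else:
        target = 10_000.0
    values = matrix.values * (target / totals)
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.spot_barcodes), values, stage="normalized"
    )


def log_transform(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """``log(value + pseudocount)`` in the configured base (stage -> log)."""
    config = config or PreprocessConfig()
    if matrix.stage != "normalized":
        raise DataError(f"log_transform expects normalized, got stage {matrix.stage!r}")
    values = np.log(matrix.values + config.pseudocount) / np.log(config.log_base)
    if not np.isfinite(values).all():
        raise DataError("log transform produced non-finite values")
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.spot_barcodes), values, stage="log")


def centralize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across spots (stage -> centralized)."""
    if matrix.stage != "log":
        raise DataError(f"centralize expects log, got stage {matrix.stage!r}")
    values = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    if not np.isfinite(values).all():
        raise DataError("centralization produced non-finite values")
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.spot_barcodes), values, stage="centralized"
    )


def log_and_centralize(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    return centralize(log_transform(matrix, config))


def preprocess(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Full pipeline: filter -> normalize -> log -> centralize."""
    config = config or PreprocessConfig()
    return log_and_centralize(normalize(filter_genes(matrix, config), config), config)


def normalized_log(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Filter + normalize + log without centralization.

    This is the scale on which "expressed / not expressed" thresholds are
    meaningful (centralized values are signed relative levels); used by the
    receptor-ligand module.
    """
    config = config or PreprocessConfig()
    return log_transform(normalize(filter_genes(matrix, config), config), config)
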