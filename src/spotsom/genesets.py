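"""Gene-set maps, per-spot gene-set scores, and module enrichment.

A gene-set map counts where a functional signature's members fall on the
trained metagene grid, for direct visual comparison with portrait
activation patterns. Module/gene-set enrichment uses the one-sided
hypergeometric test on the overlap of module gene lists with each set
(restricted to the analysis universe, by default all genes retained after
filtering), with Benjamini-Hochberg FDR across all module x set pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .segmentation import ModuleSet
from .som import SomPortrayal
from .types import DataError, ExpressionMatrix, GeneSet, GeneSetCollection


@dataclass
class GeneSetMap:
    counts: np.ndarray  # grid-shaped non-negative ints
    set_name: str

    @property
    def n_mapped(self) -> int:
        return int(self.counts.sum())


def geneset_map(model: SomPortrayal, gene_set: GeneSet) -> GeneSetMap:
    """Count set members per SOM unit (members absent from the model excluded)."""
    model._check_fitted()
    counts = np.zeros((model.grid_rows, model.grid_cols), dtype=int)
    members = set(gene_set.gene_ids)
    n_found = 0
    for g in model.gene_ids_:
        if g in members:
            r, c = model.gene_assignment_[g]
            counts[r, c] += 1
            n_found += 1
    if n_found == 0:
        warnings.warn(f"gene set {gene_set.name!r} has no members in the model", stacklevel=2)
    return GeneSetMap(counts, gene_set.name)


def geneset_spot_score(matrix: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-spot mean centralized expression over the set's present members."""
    if matrix.stage != "centralized":
        raise DataError(f"geneset_spot_score expects centralized data, got {matrix.stage!r}")
    idx = [i for i, g in enumerate(matrix.gene_ids) if g in set(gene_set.gene_ids)]
    if not idx:
        raise DataError(f"no member of gene set {gene_set.name!r} present in the matrix")
    return pd.Series(
        matrix.values[idx].mean(axis=0), index=matrix.spot_barcodes, name=gene_set.name
    )


def hypergeometric_overlap_p(overlap: int, module_size: int, set_size: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, module_size)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, module_size))


def enrich_modules(
    module_set: ModuleSet,
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of every module x gene-set pair.

    Returns a DataFrame with columns module_label, set_name, overlap,
    module_size, set_size_in_universe, universe_size, p_value, fdr
    (Benjamini-Hochberg across all tested pairs).
    """
    uni = set(universe)
    if len(uni) != len(universe):
        raise DataError("universe contains duplicate gene ids")
    rows = []
    for module in module_set:
        mod_genes = set(module.gene_ids)
        outside = mod_genes - uni
        if outside:
            raise DataError(
                f"module {module.label} has genes outside the universe: {sorted(outside)[:5]}"
            )
        for gs in collection:
            set_in_uni = set(gs.gene_ids) & uni
            overlap = len(mod_genes & set_in_uni)
            p = hypergeometric_overlap_p(overlap, len(mod_genes), len(set_in_uni), len(uni))
            rows.append(
                {
                    "module_label": module.label,
                    "set_name": gs.name,
                    "overlap": overlap,
                    "module_size": len(mod_genes),
                    "set_size_in_universe": len(set_in_uni),
                    "universe_size": len(uni),
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
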