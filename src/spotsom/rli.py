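"""Receptor-ligand co-expression calls per spot.

A spot is called ``coexpressed`` when both the receptor and the ligand
exceed the expression threshold, ``receptor_only``/``ligand_only`` when one
does, ``none`` otherwise (values exactly at the threshold count as not
expressed). The threshold applies to normalized log expression *before*
gene-centralization: centralized values are signed relative levels, whereas
"expressed vs. not expressed" is a detection statement. Color saturation of
the calls scales with expression level relative to the two genes'
matrix-wide 95th percentile.

Pathway-wide aggregation folds per-pair calls with the precedence
coexpressed > receptor_only > ligand_only > none. Spot neighborhoods use
hex distance on Visium array coordinates, where array_col parity alternates
with array_row so that (r, c) has lattice neighbors (r, c+-2) and
(r+-1, c+-1); in axial coordinates q = (col - row) / 2, r_ax = row, the hex
distance is (|dq| + |dr| + |dq + dr|) / 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import DataError, ExpressionMatrix, RLIPair, SpatialLayout

STATES = ("coexpressed", "receptor_only", "ligand_only", "none")
_PRECEDENCE = {s: i for i, s in enumerate(STATES)}


def classify_rli(
    matrix: ExpressionMatrix, pair: RLIPair, expr_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-spot interaction state, joint score, and color saturation.

    Returns a DataFrame indexed by barcode with columns ``state``,
    ``joint_score`` (mean of the two expression values where coexpressed,
    else 0) and ``saturation`` in [0, 1].
    """
    r = matrix.gene_values(pair.receptor_gene)  # DataError if absent, naming the gene
    l = matrix.gene_values(pair.ligand_gene)
    r_on, l_on = r > expr_threshold, l > expr_threshold
    state = np.where(
        r_on & l_on, "coexpressed",
        np.where(r_on, "receptor_only", np.where(l_on, "ligand_only", "none")),
    )
    joint = np.where(r_on & l_on, (r + l) / 2.0, 0.0)
    relevant = np.where(
        r_on & l_on, (r + l) / 2.0, np.where(r_on, r, np.where(l_on, l, 0.0))
    )
    p95 = float(np.percentile(np.concatenate([r, l]), 95))
    if p95 > 0:
        saturation = np.minimum(1.0, np.maximum(relevant, 0.0) / p95)
    else:
        saturation = (relevant > 0).astype(float)
    return pd.DataFrame(
        {"state": state, "joint_score": joint, "saturation": saturation},
        index=pd.Index(matrix.spot_barcodes, name="barcode"),
    )


def pathway_rli_map(
    matrix: ExpressionMatrix, pairs: list[RLIPair], expr_threshold: float = 0.0
) -> pd.DataFrame:
    """Aggregate calls over a pair collection (e.g. one pathway's pairs).

    Per spot: coexpressed if any pair is coexpressed (joint_score = max over
    those pairs, best pair recorded), else receptor_only if any, else
    ligand_only if any, else none.
    """
    present = []
    gene_set = set(matrix.gene_ids)
    for p in pairs:
        if p.receptor_gene in gene_set and p.ligand_gene in gene_set:
            present.append(p)
        else:
            warnings.warn(f"pair {p.name} skipped: gene(s) absent from matrix", stacklevel=2)
    if not present:
        raise DataError("no receptor-ligand pair has both genes in the matrix")
    calls = {p.name: classify_rli(matrix, p, expr_threshold) for p in present}
    barcodes = matrix.spot_barcodes
    state_out, score_out, best_out, sat_out = [], [], [], []
    for b in barcodes:
        best_state = "none"
        best_score, best_pair, best_sat = 0.0, "", 0.0
        for p in present:
            row = calls[p.name].loc[b]
            if _PRECEDENCE[row["state"]] < _PRECEDENCE[best_state]:
                best_state = row["state"]
                best_sat = float(row["saturation"])
                best_pair = p.name if row["state"] == "coexpressed" else best_pair
                best_score = float(row["joint_score"])
            elif row["state"] == best_state == "coexpressed" and row["joint_score"] > best_score:
                best_score = float(row["joint_score"])
                best_pair = p.name
                best_sat = float(row["saturation"])
        state_out.append(best_state)
        score_out.append(best_score)
        best_out.append(best_pair)
        sat_out.append(best_sat)
    return pd.DataFrame(
        {"state": state_out, "joint_score": score_out, "saturation": sat_out,
         "best_pair": best_out},
        index=pd.Index(barcodes, name="barcode"),
    )


def rank_rli_pairs(
    matrix: ExpressionMatrix, barcode: str, pairs: list[RLIPair]
) -> list[tuple[RLIPair, float]]:
    """Pairs ordered by descending joint (mean) expression in one spot.

    Ties are broken by pair name lexicographically; pairs with absent genes
    are skipped with a warning.
    """
    j = matrix.spot_index(barcode)
    gene_set = set(matrix.gene_ids)
    scored = []
    for p in pairs:
        if p.receptor_gene not in gene_set or p.ligand_gene not in gene_set:
            warnings.warn(f"pair {p.name} skipped: gene(s) absent from matrix", stacklevel=2)
            continue
        score = (matrix.gene_values(p.receptor_gene)[j] + matrix.gene_values(p.ligand_gene)[j]) / 2.0
        scored.append((p, float(score)))
    return sorted(scored, key=lambda t: (-t[1], t[0].name))


def _axial(row: int, col: int) -> tuple[float, int]:
    return ((col - row) / 2.0, row)


def hex_distance(row1: int, col1: int, row2: int, col2: int) -> int:
    """Steps between two spots on the Visium hex lattice (array coordinates)."""
    q1, r1 = _axial(row1, col1)
    q2, r2 = _axial(row2, col2)
    dq, dr = q1 - q2, r1 - r2
    return int(round((abs(dq) + abs(dr) + abs(dq + dr)) / 2.0))


def rli_neighborhood(layout: SpatialLayout, barcode: str, ring: int) -> list[str]:
    """In-tissue barcodes within ``ring`` hex steps of a spot (incl. itself)."""
    if ring < 0:
        raise DataError("ring must be >= 0")
    pos = layout.position(barcode)  # DataError if unknown
    r0, c0 = int(pos["array_row"]), int(pos["array_col"])
    out = []
    for b in layout.in_tissue_barcodes:
        p = layout.table.loc[b]
        if hex_distance(r0, c0, int(p["array_row"]), int(p["array_col"])) <= ring:
            out.append(b)
    return out
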