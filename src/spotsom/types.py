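"""Core in-memory containers shared across the package.

The central object is the :class:`ExpressionMatrix`, a genes x spots value
matrix that moves through a staged preprocessing pipeline
(``raw_counts -> normalized -> log -> centralized``) before SOM training.
Spatial information lives in a :class:`SpatialLayout` on the Visium hex
lattice; gene annotations (gene sets, receptor-ligand pairs, signed pathway
graphs) have small dedicated containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised on malformed, inconsistent, or missing input data."""


STAGES = ("raw_counts", "normalized", "log", "centralized")


def _check_unique(items, what: str) -> None:
    if len(set(items)) != len(items):
        seen, dups = set(), []
        for x in items:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise DataError(f"duplicate {what}: {dups[:5]}{'...' if len(dups) > 5 else ''}")


@dataclass
class ExpressionMatrix:
    """Genes x spots expression values with identifiers and a pipeline stage.

    Parameters
    ----------
    gene_ids
        Row identifiers (symbols or Ensembl IDs); must be unique.
    spot_barcodes
        Column identifiers (spot barcodes); must be unique.
    values
        ``(n_genes, n_spots)`` float array.
    stage
        One of ``raw_counts``, ``normalized``, ``log``, ``centralized``.
        ``raw_counts`` requires non-negative integer values.
    """

    gene_ids: list[str]
    spot_barcodes: list[str]
    values: np.ndarray
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.spot_barcodes = [str(b).strip() for b in self.spot_barcodes]
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.spot_barcodes, "spot_barcodes")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_barcodes)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_barcodes)} spots"
            )
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "raw_counts":
            if self.values.size and (
                (self.values < 0).any() or not np.allclose(self.values, np.round(self.values))
            ):
                raise DataError("raw_counts stage requires non-negative integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_barcodes)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present in matrix") from None

    def spot_index(self, barcode: str) -> int:
        try:
            return self.spot_barcodes.index(barcode)
        except ValueError:
            raise DataError(f"spot barcode {barcode!r} not present in matrix") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.gene_ids[i] for i in keep],
            list(self.spot_barcodes),
            self.values[keep],
            stage=self.stage,
        )

    def subset_spots(self, barcodes: list[str]) -> "ExpressionMatrix":
        idx = [self.spot_index(b) for b in barcodes]
        return ExpressionMatrix(
            list(self.gene_ids), list(barcodes), self.values[:, idx], stage=self.stage
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.spot_barcodes)


@dataclass
class SpatialLayout:
    """Per-spot positions on the Visium hex lattice.

    ``table`` is indexed by barcode with columns ``in_tissue`` (bool),
    ``array_row``, ``array_col`` (ints; col parity alternates with row parity
    on the hex lattice) and ``pixel_x``, ``pixel_y`` (full-resolution image
    coordinates).
    """

    table: pd.DataFrame

    REQUIRED = ("in_tissue", "array_row", "array_col", "pixel_x", "pixel_y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"layout table missing columns {missing}")
        if self.table.index.has_duplicates:
            raise DataError("duplicate barcodes in spatial layout")
        t = self.table
        if (t[["array_row", "array_col"]] < 0).to_numpy().any():
            raise DataError("array coordinates must be non-negative")
        it = t[t["in_tissue"].astype(bool)]
        if it.duplicated(subset=["array_row", "array_col"]).any():
            raise DataError("duplicate (array_row, array_col) among in-tissue spots")

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    @property
    def in_tissue_barcodes(self) -> list[str]:
        m = self.table["in_tissue"].astype(bool)
        return list(self.table.index[m])

    def position(self, barcode: str) -> pd.Series:
        try:
            return self.table.loc[barcode]
        except KeyError:
            raise DataError(f"barcode {barcode!r} not present in layout") from None


@dataclass
class SpotLabels:
    """User-supplied spot annotation (cluster ids or cell types)."""

    labels: dict[str, str]
    label_kind: str = "cluster"

    def __post_init__(self) -> None:
        if self.label_kind not in ("cluster", "cell_type"):
            raise DataError(f"label_kind {self.label_kind!r} not in {{cluster, cell_type}}")

    def barcodes_for(self, label: str) -> list[str]:
        return [b for b, l in self.labels.items() if l == label]

    @property
    def unique_labels(self) -> list[str]:
        return sorted(set(self.labels.values()))


@dataclass
class GeneSet:
    name: str
    category: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError(f"gene set {self.name!r} has an empty gene list")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set names")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise DataError(f"gene set {name!r} not in collection")


@dataclass(frozen=True)
class RLIPair:
    """A receptor gene / ligand gene pair, optionally tagged with pathways."""

    receptor_gene: str
    ligand_gene: str
    pathway_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.receptor_gene and self.ligand_gene and self.receptor_gene == self.ligand_gene:
            raise DataError(f"receptor and ligand are the same gene {self.receptor_gene!r}")

    @property
    def name(self) -> str:
        return f"{self.receptor_gene}_{self.ligand_gene}"


@dataclass
class PathwayGraph:
    """Signed directed pathway topology.

    Edges carry ``sign`` in {+1, -1} (activation / inhibition). Sources and
    sinks default to in-degree-0 / out-degree-0 nodes unless declared.
    """

    graph: nx.DiGraph
    sources: list[str] = field(default_factory=list)
    sinks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d.get("sign") not in (1, -1):
                raise DataError(f"edge {u}->{v} has sign {d.get('sign')!r}, expected +1/-1")
        if not self.sources:
            self.sources = sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)
        if not self.sinks:
            self.sinks = sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)
        for n in list(self.sources) + list(self.sinks):
            if n not in self.graph:
                raise DataError(f"declared source/sink {n!r} not a node of the graph")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)]
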