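"""Readers and writers for all external formats.

Visium-style directories (Matrix Market counts + barcodes + features +
tissue positions, gzip allowed), GMT gene-set collections, receptor-ligand
TSV tables, signed pathway edge lists, and the package's own model archive
(a zip with a JSON manifest).

Both tissue-positions dialects are supported: the older headerless
six-column ``tissue_positions_list.csv`` and the headered
``tissue_positions.csv``; the dialect is auto-detected from the first line.
The count matrix is canonicalized to genes x spots regardless of on-disk
orientation (detected by matching the barcode list length).
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
import scipy.sparse

from .types import (
    DataError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PathwayGraph,
    RLIPair,
    SpatialLayout,
    SpotLabels,
)

MODEL_FORMAT_VERSION = 1

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pixel_y", "pixel_x"]
# headered Space Ranger order: barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres
# pxl_row is the vertical (y) image coordinate, pxl_col the horizontal (x).


def _find(directory: Path, *names: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise DataError(f"missing file: none of {names} found in {directory}")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_tissue_positions(path: Path | str) -> SpatialLayout:
    """Parse a tissue-positions CSV in either Space Ranger dialect."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    rows = []
    with _open_maybe_gzip(path) as fh:
        reader = csv.reader(fh)
        header_skipped = False
        for lineno, fields in enumerate(reader, start=1):
            if not fields or all(not f.strip() for f in fields):
                continue
            if lineno == 1 and fields[0].strip().lower() == "barcode":
                header_skipped = True
                continue
            if len(fields) != 6:
                raise DataError(f"{path} line {lineno}: expected 6 fields, got {len(fields)}")
            try:
                rows.append(
                    {
                        "barcode": fields[0].strip(),
                        "in_tissue": bool(int(fields[1])),
                        "array_row": int(fields[2]),
                        "array_col": int(fields[3]),
                        "pixel_y": float(fields[4]),
                        "pixel_x": float(fields[5]),
                    }
                )
            except ValueError as exc:
                raise DataError(f"{path} line {lineno}: malformed row ({exc})") from None
        del header_skipped
    if not rows:
        raise DataError(f"{path}: no position rows found")
    table = pd.DataFrame(rows).set_index("barcode")
    return SpatialLayout(table)


def read_visium(
    directory: Path | str, alias_map: dict[str, str] | None = None
) -> tuple[ExpressionMatrix, SpatialLayout]:
    """Read a Visium-style directory into a raw-count matrix and layout.

    Expects ``matrix.mtx(.gz)``, ``barcodes.tsv(.gz)``, ``features.tsv(.gz)``
    (in the directory or a ``filtered_feature_bc_matrix`` subdirectory) and a
    tissue-positions CSV (in the directory or a ``spatial`` subdirectory).
    The returned matrix is restricted to barcodes present in both the matrix
    and the layout; a warning reports any mismatch beyond the intersection.

    Gene identifiers are matched case-sensitively after whitespace stripping;
    ``alias_map`` optionally translates on-disk ids (e.g. Ensembl) to the id
    space used downstream (e.g. symbols) at read time.
    """
    directory = Path(directory)
    sub = directory / "filtered_feature_bc_matrix"
    mdir = sub if sub.is_dir() else directory
    mtx_path = _find(mdir, "matrix.mtx", "matrix.mtx.gz")
    barcodes_path = _find(mdir, "barcodes.tsv", "barcodes.tsv.gz")
    features_path = _find(mdir, "features.tsv", "features.tsv.gz")
    spatial = directory / "spatial"
    pdir = spatial if spatial.is_dir() else directory
    pos_path = _find(
        pdir,
        "tissue_positions.csv",
        "tissue_positions_list.csv",
        "tissue_positions.csv.gz",
        "tissue_positions_list.csv.gz",
    )

    barcodes = [l.split("\t")[0].strip() for l in _read_lines(barcodes_path)]
    feature_rows = [l.split("\t") for l in _read_lines(features_path)]
    gene_ids = [r[0].strip() for r in feature_rows]
    if alias_map:
        gene_ids = [alias_map.get(g, g) for g in gene_ids]

    with _open_maybe_gzip(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat).toarray()
    if mat.shape == (len(gene_ids), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(gene_ids)):
        mat = mat.T
    else:
        raise DataError(
            f"matrix shape {mat.shape} matches neither {len(gene_ids)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )

    layout = read_tissue_positions(pos_path)
    common = [b for b in barcodes if b in set(layout.barcodes)]
    n_only_matrix = len(barcodes) - len(common)
    n_only_layout = len(layout.barcodes) - len(common)
    if n_only_matrix or n_only_layout:
        warnings.warn(
            f"barcode mismatch: {n_only_matrix} only in matrix, "
            f"{n_only_layout} only in positions; using {len(common)} common barcodes",
            stacklevel=2,
        )
    if not common:
        raise DataError("no barcodes shared between matrix and tissue positions")
    col_idx = {b: j for j, b in enumerate(barcodes)}
    em = ExpressionMatrix(
        gene_ids, common, mat[:, [col_idx[b] for b in common]], stage="raw_counts"
    )
    return em, layout


def write_visium(
    directory: Path | str,
    matrix: ExpressionMatrix,
    layout: SpatialLayout,
    headered_positions: bool = True,
) -> Path:
    """Write a Visium-style fixture directory that :func:`read_visium` reads back."""
    directory = Path(directory)
    (directory / "spatial").mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values)
    with open(directory / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, sparse, field="integer" if matrix.stage == "raw_counts" else "real")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.spot_barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.gene_ids)
    )
    pos = directory / "spatial" / ("tissue_positions.csv" if headered_positions else "tissue_positions_list.csv")
    with open(pos, "w", newline="") as fh:
        writer = csv.writer(fh)
        if headered_positions:
            writer.writerow(
                ["barcode", "in_tissue", "array_row", "array_col",
                 "pxl_row_in_fullres", "pxl_col_in_fullres"]
            )
        for barcode, row in layout.table.iterrows():
            writer.writerow(
                [barcode, int(row["in_tissue"]), int(row["array_row"]),
                 int(row["array_col"]), row["pixel_y"], row["pixel_x"]]
            )
    return directory


def read_labels(path: Path | str, label_kind: str = "cluster") -> SpotLabels:
    """Read a two-column barcode,label CSV/TSV (header optional)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).strip().lower() in ("barcode", "spot"):
        df = df.iloc[1:]
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        barcode = str(row.iloc[0]).strip()
        if barcode in labels:
            raise DataError(f"barcode {barcode!r} appears more than once in {path}")
        labels[barcode] = str(row.iloc[1]).strip()
    return SpotLabels(labels, label_kind=label_kind)


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name  description  gene1  gene2 ...``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    sets: list[GeneSet] = []
    names: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path} line {lineno}: GMT line has {len(fields)} fields (<3)")
            name, category = fields[0].strip(), fields[1].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise DataError(f"{path} line {lineno}: gene set {name!r} has no genes")
            if name in names:
                raise DataError(f"{path} line {lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, category, genes))
    return GeneSetCollection(sets)


def write_gmt(path: Path | str, collection: GeneSetCollection) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.category or "na", *s.gene_ids]) + "\n")
    return path


def read_rli_table(
    path: Path | str,
    receptor_col: str = "receptor",
    ligand_col: str = "ligand",
    pathway_col: str = "pathway",
    tag_delimiter: str = ";",
) -> list[RLIPair]:
    """Read an omnipath-style receptor-ligand TSV, deduplicating pairs.

    Duplicate (receptor, ligand) rows are collapsed; their pathway tags are
    merged. The pathway column is optional.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in (receptor_col, ligand_col):
        if col not in df.columns:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    merged: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        key = (str(row[receptor_col]).strip(), str(row[ligand_col]).strip())
        tags = []
        if pathway_col in df.columns and str(row[pathway_col]).strip():
            tags = [t.strip() for t in str(row[pathway_col]).split(tag_delimiter) if t.strip()]
        if key not in merged:
            merged[key] = []
            order.append(key)
        for t in tags:
            if t not in merged[key]:
                merged[key].append(t)
    return [
        RLIPair(receptor_gene=r, ligand_gene=l, pathway_tags=tuple(merged[(r, l)]))
        for r, l in order
    ]


_SIGN_WORDS = {
    "1": 1, "+1": 1, "activation": 1, "activate": 1, "+": 1,
    "-1": -1, "inhibition": -1, "inhibit": -1, "-": -1,
}


def read_pathway_graph(
    path: Path | str,
    sources: list[str] | None = None,
    sinks: list[str] | None = None,
) -> PathwayGraph:
    """Read a signed directed edge list TSV: ``source  target  sign``.

    Sign accepts +1/-1 or the keywords ``activation``/``inhibition``.
    Sources/sinks default to in-degree-0 / out-degree-0 nodes.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    graph = nx.DiGraph()
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in ("source", "from"):
                continue
            if len(fields) < 3:
                raise DataError(f"{path} line {lineno}: expected 3 fields, got {len(fields)}")
            raw_sign = fields[2].strip().lower()
            if raw_sign not in _SIGN_WORDS:
                raise DataError(
                    f"{path} line {lineno}: sign {fields[2]!r} not in "
                    "{+1, -1, activation, inhibition}"
                )
            graph.add_edge(fields[0].strip(), fields[1].strip(), sign=_SIGN_WORDS[raw_sign])
    return PathwayGraph(graph, sources=list(sources or []), sinks=list(sinks or []))


def save_model(model, path: Path | str) -> Path:
    """Serialize a fitted :class:`~spotsom.som.SomPortrayal` to a zip archive.

    The archive holds a JSON manifest (format version, estimator params,
    identifier lists) plus the weight tensor and gene->unit assignment as
    ``.npy`` members; :func:`load_model` restores it bit-exactly.
    """
    from .som import SomPortrayal  # local import to avoid a cycle

    if not isinstance(model, SomPortrayal) or not hasattr(model, "weights_"):
        raise DataError("save_model requires a fitted SomPortrayal")
    path = Path(path)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "gene_ids": model.gene_ids_,
        "spot_barcodes": model.spot_barcodes_,
        "quantization_error": float(model.quantization_error_),
        "initial_quantization_error": float(model.initial_quantization_error_),
    }
    assignment = np.array([model.gene_assignment_[g] for g in model.gene_ids_], dtype=np.int64)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        for name, arr in (("weights.npy", model.weights_), ("assignment.npy", assignment)):
            buf = _stdio.BytesIO()
            np.save(buf, arr)
            zf.writestr(name, buf.getvalue())
    return path


def load_model(path: Path | str):
    """Restore a :class:`~spotsom.som.SomPortrayal` saved by :func:`save_model`."""
    from .som import SomPortrayal

    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            weights = np.load(_stdio.BytesIO(zf.read("weights.npy")))
            assignment = np.load(_stdio.BytesIO(zf.read("assignment.npy")))
    except (zipfile.BadZipFile, KeyError, EOFError, ValueError) as exc:
        raise DataError(f"corrupt or truncated model archive {path}: {exc}") from None
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DataError(
            f"model archive format version {version} does not match "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    model = SomPortrayal(**manifest["params"])
    model._restore(
        weights=weights,
        gene_ids=manifest["gene_ids"],
        spot_barcodes=manifest["spot_barcodes"],
        assignment=assignment,
        quantization_error=manifest["quantization_error"],
        initial_quantization_error=manifest["initial_quantization_error"],
    )
    return model
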