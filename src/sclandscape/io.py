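"""Data model and disk I/O for 10x-style count matrices.

The on-disk layout is a MatrixMarket "trio" — a coordinate-format integer
matrix (genes x cells) plus one-entry-per-line features and barcodes files —
with a per-cell metadata TSV (columns ``barcode``, ``patient``, ``group``,
``cluster``).  Optional spliced/unspliced layers are additional MTX files
sharing both axes, referenced from a YAML manifest together with an optional
cells x 2 embedding TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

GROUPS = ("WT", "MT")
META_COLUMNS = ("patient", "group", "cluster")


class ValidationError(ValueError):
    """Input violates a semantic contract (bad labels, duplicates, zeros)."""


class FormatError(ValueError):
    """Input file does not match its declared format."""


@dataclass
class AnnotatedCounts:
    """Sparse gene x cell raw UMI counts with per-cell annotations.

    Attributes
    ----------
    counts : scipy.sparse.csc_matrix
        Non-negative integer counts, genes on rows, cells on columns.
    gene_ids, cell_ids : list of str
        Unique axis identifiers.
    cell_meta : pandas.DataFrame
        Indexed by barcode, columns ``patient``, ``group`` (WT/MT),
        ``cluster`` (e.g. C0..C17).
    layers : dict
        Optional named matrices (``spliced``, ``unspliced``) congruent
        with ``counts``.
    embedding : ndarray or None
        Optional cells x 2 coordinates (precomputed; never computed here).
    """

    counts: sp.csc_matrix
    gene_ids: list
    cell_ids: list
    cell_meta: pd.DataFrame
    layers: dict = field(default_factory=dict)
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {g} matrix rows")
        if len(self.cell_ids) != c:
            raise FormatError(f"{len(self.cell_ids)} barcodes for {c} matrix columns")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValidationError("duplicate barcodes")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        missing = [b for b in self.cell_ids if b not in self.cell_meta.index]
        if missing:
            raise ValidationError(f"barcodes absent from metadata: {missing[:5]}")
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta missing column {col!r}")
        self.cell_meta = self.cell_meta.loc[self.cell_ids, list(META_COLUMNS)]
        if self.cell_meta[["group", "cluster"]].isna().any().any():
            raise ValidationError("every cell needs exactly one group and cluster")
        for name, layer in self.layers.items():
            layer = sp.csc_matrix(layer)
            if layer.shape != self.counts.shape:
                raise ValidationError(
                    f"layer {name!r} shape {layer.shape} != counts shape {self.counts.shape}"
                )
            self.layers[name] = layer
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if self.embedding.shape != (c, 2):
                raise ValidationError("embedding must be cells x 2")


def _read_lines(path) -> list:
    lines = [ln.split("\t")[0] for ln in Path(path).read_text().splitlines() if ln.strip()]
    return lines


def read_mtx_trio(matrix_path, features_path, barcodes_path, meta_path) -> AnnotatedCounts:
    """Read a MatrixMarket trio plus metadata TSV into :class:`AnnotatedCounts`.

    MTX indices are 1-based on disk, 0-based in memory (scipy handles the
    shift).  Barcodes absent from the metadata cause rejection.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    genes = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"MTX declares {mat.shape[0]} genes but features file has {len(genes)} lines"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {mat.shape[1]} cells but barcodes file has {len(barcodes)} lines"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        raise FormatError("metadata TSV must have a 'barcode' column")
    if meta["barcode"].duplicated().any():
        raise ValidationError("duplicate barcodes in metadata")
    meta = meta.set_index("barcode")
    return AnnotatedCounts(mat, genes, barcodes, meta)


def write_mtx_trio(ac: AnnotatedCounts, out_dir, prefix: str = "") -> dict:
    """Write counts + features + barcodes + metadata; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}matrix.mtx",
        "features": out / f"{prefix}features.tsv",
        "barcodes": out / f"{prefix}barcodes.tsv",
        "meta": out / f"{prefix}cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(ac.counts), field="integer")
    paths["features"].write_text("\n".join(map(str, ac.gene_ids)) + "\n")
    paths["barcodes"].write_text("\n".join(map(str, ac.cell_ids)) + "\n")
    ac.cell_meta.rename_axis("barcode").reset_index().to_csv(
        paths["meta"], sep="\t", index=False
    )
    for name, layer in ac.layers.items():
        p = out / f"{prefix}{name}.mtx"
        scipy.io.mmwrite(str(p), sp.coo_matrix(layer), field="integer")
        paths[name] = p
    if ac.embedding is not None:
        p = out / f"{prefix}embedding.tsv"
        pd.DataFrame(ac.embedding, index=ac.cell_ids, columns=["x", "y"]).rename_axis(
            "barcode"
        ).to_csv(p, sep="\t")
        paths["embedding"] = p
    return {k: str(v) for k, v in paths.items()}


def write_manifest(paths: dict, manifest_path) -> str:
    """Record a trio (and optional layers/embedding) in a YAML manifest."""
    Path(manifest_path).write_text(yaml.safe_dump({"files": paths}, sort_keys=True))
    return str(manifest_path)


def read_manifest(manifest_path) -> AnnotatedCounts:
    """Load an :class:`AnnotatedCounts` (with layers/embedding) from a manifest."""
    spec = yaml.safe_load(Path(manifest_path).read_text())["files"]
    ac = read_mtx_trio(spec["matrix"], spec["features"], spec["barcodes"], spec["meta"])
    for name in ("spliced", "unspliced"):
        if name in spec:
            layer = sp.csc_matrix(scipy.io.mmread(spec[name]))
            ac.layers[name] = layer
    if "embedding" in spec:
        emb = pd.read_csv(spec["embedding"], sep="\t", index_col="barcode")
        ac.embedding = emb.loc[ac.cell_ids, ["x", "y"]].to_numpy(float)
    ac.validate()
    return ac


def patient_dominance_warnings(cell_meta: pd.DataFrame, max_share: float = 0.5) -> list:
    """Flag clusters where a single patient contributes more than ``max_share``.

    Composition testing treats cells as independent draws; clusters dominated
    by one patient are pseudo-replicated and merit exclusion from
    interpretation (the caveat is logged, not enforced).
    """
    notes = []
    for cluster, sub in cell_meta.groupby("cluster", observed=True):
        share = sub["patient"].value_counts(normalize=True)
        if share.iloc[0] > max_share:
            notes.append(
                f"cluster {cluster}: patient {share.index[0]} contributes "
                f"{share.iloc[0]:.0%} of cells"
            )
            warnings.warn(notes[-1])
    return notes
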