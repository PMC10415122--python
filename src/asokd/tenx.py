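"""10x-style MatrixMarket I/O and metadata reading.

Reads and writes the triplet layout of ``matrix.mtx[.gz]`` +
``features.tsv[.gz]`` + ``barcodes.tsv[.gz]`` (1-based MatrixMarket indices;
features file with feature id and gene symbol columns).  On-disk orientation
is normalized to cells x genes on read, inferred from the lengths of the
barcodes and features files.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import ARMS, CountData, validate_metadata
from .errors import FormatError, SchemaError


def _open_maybe_gz(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: str, stem: str) -> str:
    for name in (f"{stem}.gz", stem):
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            return p
    raise FormatError(f"no {stem}[.gz] found in {dirpath}")


@dataclass
class TenxCounts:
    """A cells x genes sparse UMI matrix with barcodes and feature table."""

    matrix: sparse.csr_matrix  # cells x genes
    barcodes: list[str]
    features: pd.DataFrame  # columns: feature_id, symbol

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def totals(self) -> np.ndarray:
        """Per-cell total UMIs from a full sparse re-summation (explicit
        zeros contribute nothing)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    def gene_index(self, gene: str) -> int:
        """Locate a gene by feature id, then by symbol; ambiguity is an error."""
        for col in ("feature_id", "symbol"):
            hits = np.flatnonzero(self.features[col].to_numpy() == gene)
            if len(hits) == 1:
                return int(hits[0])
            if len(hits) > 1:
                raise SchemaError(f"gene {gene!r} matches {len(hits)} features by {col}")
        raise SchemaError(f"target gene {gene!r} not found in features")

    def target_counts(self, gene: str) -> np.ndarray:
        j = self.gene_index(gene)
        return np.asarray(self.matrix[:, j].todense()).ravel().astype(np.int64)

    def extract(self, gene: str) -> CountData:
        """Target + total counts for downstream modelling."""
        return CountData(
            target_umi=self.target_counts(gene),
            total_umi=self.totals(),
            barcodes=list(self.barcodes),
        )


def read_counts_10x(path: str) -> TenxCounts:
    """Read a 10x triplet directory (or an explicit matrix file path).

    Accepts plain or gzipped files.  Raises :class:`FormatError` when the
    matrix header disagrees with the lengths of the features/barcodes files
    or the file is truncated/corrupt.
    """
    if os.path.isdir(path):
        mtx_path = _find(path, "matrix.mtx")
        feat_path = _find(path, "features.tsv")
        bc_path = _find(path, "barcodes.tsv")
    else:
        d = os.path.dirname(path) or "."
        mtx_path, feat_path, bc_path = path, _find(d, "features.tsv"), _find(d, "barcodes.tsv")

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    features = pd.DataFrame({"feature_id": feats[0], "symbol": feats[1]})
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]

    try:
        with _open_maybe_gz(mtx_path, "rb") as fh:
            mat = spio.mmread(io.BytesIO(fh.read()))
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc

    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        mat = mat.T  # standard 10x orientation: genes x cells on disk
    elif mat.shape == (n_bc, n_feat):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} in {mtx_path} matches neither "
            f"features x barcodes ({n_feat} x {n_bc}) nor its transpose"
        )
    return TenxCounts(
        matrix=sparse.csr_matrix(mat, dtype=np.int64),
        barcodes=barcodes,
        features=features,
    )


def write_10x(dirpath: str, counts: TenxCounts, compress: bool = True) -> None:
    """Write a 10x triplet directory (genes x cells on disk, 1-based indices)."""
    os.makedirs(dirpath, exist_ok=True)
    suffix = ".gz" if compress else ""
    buf = io.BytesIO()
    spio.mmwrite(buf, sparse.coo_matrix(counts.matrix.T), field="integer")
    with _open_maybe_gz(os.path.join(dirpath, f"matrix.mtx{suffix}"), "wb") as fh:
        fh.write(buf.getvalue())
    with _open_maybe_gz(os.path.join(dirpath, f"features.tsv{suffix}"), "wt") as fh:
        for _, r in counts.features.iterrows():
            fh.write(f"{r['feature_id']}\t{r['symbol']}\tGene Expression\n")
    with _open_maybe_gz(os.path.join(dirpath, f"barcodes.tsv{suffix}"), "wt") as fh:
        fh.write("\n".join(counts.barcodes) + "\n")


def read_metadata(path: str, arms: tuple[str, str] = ARMS) -> pd.DataFrame:
    """Read and validate the cell metadata TSV.

    Required columns: barcode, animal, arm, cell_type; extra columns are
    preserved.  Duplicate barcodes and unknown arm labels are rejected.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"barcode": str, "animal": str,
                                              "arm": str, "cell_type": str})
    return validate_metadata(meta, arms=arms)


def write_metadata(path: str, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)
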