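"""Core in-memory containers: per-cell counts and cell metadata.

``CountData`` carries, for every cell, the UMI count of the ASO's target gene
and the total UMI count of the cell — the minimal substrate of the whole
analysis.  Cell metadata (barcode, animal, treatment arm, cell type) travels
as a plain :class:`pandas.DataFrame` validated by :func:`validate_metadata`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, SchemaError

ARMS = ("vehicle", "treated")
META_COLUMNS = ("barcode", "animal", "arm", "cell_type")


@dataclass
class CountData:
    """Per-cell target and total UMI counts, aligned index-wise with metadata.

    Invariants: ``0 <= target_umi[i] <= total_umi[i]`` and ``total_umi > 0``.
    """

    target_umi: np.ndarray
    total_umi: np.ndarray
    barcodes: list[str] | None = field(default=None)

    def __post_init__(self):
        self.target_umi = np.asarray(self.target_umi, dtype=np.int64)
        self.total_umi = np.asarray(self.total_umi, dtype=np.int64)
        if self.target_umi.shape != self.total_umi.shape:
            raise ValueError("target_umi and total_umi must have equal length")
        if np.any(self.total_umi <= 0):
            raise ValueError("total_umi must be positive for every cell")
        if np.any(self.target_umi < 0) or np.any(self.target_umi > self.total_umi):
            raise ValueError("target_umi must satisfy 0 <= target <= total per cell")
        if self.barcodes is not None and len(self.barcodes) != self.target_umi.size:
            raise ValueError("barcodes length does not match counts")

    @property
    def n_cells(self) -> int:
        return int(self.target_umi.size)

    def __len__(self) -> int:
        return self.n_cells


def validate_metadata(meta: pd.DataFrame, arms: tuple[str, str] = ARMS) -> pd.DataFrame:
    """Check the metadata schema: required columns, unique barcodes, known arms."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata is missing required columns: {missing}")
    dup = meta["barcode"][meta["barcode"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate barcodes in metadata: {sorted(set(dup))[:10]}")
    bad_arm = set(meta["arm"].unique()) - set(arms)
    if bad_arm:
        raise SchemaError(f"unknown arm labels {sorted(bad_arm)}; expected {arms}")
    if meta["cell_type"].isna().any() or (meta["cell_type"].astype(str) == "").any():
        raise SchemaError("every cell must have a non-empty cell_type")
    return meta


def align_counts_to_metadata(counts: CountData, meta: pd.DataFrame) -> CountData:
    """Reorder ``counts`` to the row order of ``meta`` by barcode.

    Raises :class:`DataIntegrityError` listing the offending barcodes when the
    two sides do not describe the same set of cells.
    """
    if counts.barcodes is None:
        if len(counts) != len(meta):
            raise DataIntegrityError(
                f"counts ({len(counts)} cells) and metadata ({len(meta)} rows) "
                "differ in length and counts carry no barcodes to align by"
            )
        return counts
    cset, mset = set(counts.barcodes), set(meta["barcode"])
    if cset != mset:
        only_counts = sorted(cset - mset)[:10]
        only_meta = sorted(mset - cset)[:10]
        raise DataIntegrityError(
            "barcode mismatch between counts and metadata; "
            f"examples only in counts: {only_counts}; only in metadata: {only_meta}"
        )
    pos = {b: i for i, b in enumerate(counts.barcodes)}
    order = np.array([pos[b] for b in meta["barcode"]], dtype=np.int64)
    return CountData(
        target_umi=counts.target_umi[order],
        total_umi=counts.total_umi[order],
        barcodes=list(meta["barcode"]),
    )


def warn_if_empty(obj, what: str) -> None:
    if len(obj) == 0:
        warnings.warn(f"empty {what}", stacklevel=3)
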