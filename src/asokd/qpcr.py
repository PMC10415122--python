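"""Bulk-tissue qPCR reduction (delta-delta-Ct) and single-cell concordance.

Relative quantification by the standard ddCt procedure: duplicate wells are
averaged, each sample's target Ct is normalized to a housekeeping gene
(delta Ct), then to the mean delta Ct of vehicle-treated samples
(delta-delta Ct); residual target is 2**(-ddCt), so vehicle samples average
to 1.0 on the log2 scale by construction.  Amplification efficiency is fixed
at 2.0 per cycle (no efficiency correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

QPCR_COLUMNS = ("sample", "group", "assay", "ct")
ASSAYS = ("target", "housekeeping")


def delta_delta_ct(records: pd.DataFrame, vehicle_label: str = "vehicle") -> pd.DataFrame:
    """Reduce a well-level Ct table to per-sample residual fractions.

    ``records`` columns: sample, group (vehicle/treated), assay
    (target/housekeeping), ct; one row per well, duplicates averaged before
    delta Ct.  Returns one row per sample with delta_ct, ddct and residual.
    """
    missing = [c for c in QPCR_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"qPCR table missing columns: {missing}")
    bad_assay = set(records["assay"]) - set(ASSAYS)
    if bad_assay:
        raise SchemaError(f"unknown assay labels: {sorted(bad_assay)}")
    ct = pd.to_numeric(records["ct"], errors="raise")
    if ((ct <= 0) | (ct >= 45)).any():
        raise SchemaError("Ct values must lie in (0, 45)")
    if vehicle_label not in set(records["group"]):
        raise ValueError(f"need at least one {vehicle_label!r} sample")

    per = (records.groupby(["sample", "group", "assay"], observed=True)["ct"]
           .mean().unstack("assay"))
    for assay in ASSAYS:
        if assay not in per.columns or per[assay].isna().any():
            bad = sorted(per.index[per.get(assay, pd.Series(np.nan, index=per.index))
                                   .isna()].get_level_values("sample"))
            raise SchemaError(f"samples missing {assay} wells: {bad}")
    per = per.reset_index()
    per["delta_ct"] = per["target"] - per["housekeeping"]
    vehicle_mean = per.loc[per["group"] == vehicle_label, "delta_ct"].mean()
    per["ddct"] = per["delta_ct"] - vehicle_mean
    per["residual"] = 2.0 ** (-per["ddct"])
    return per[["sample", "group", "delta_ct", "ddct", "residual"]]


@dataclass
class Concordance:
    """Agreement of bulk and aggregated single-cell residual measurements."""

    bulk_mean: float
    bulk_ci: tuple[float, float]
    sc_mean: float
    sc_ci: tuple[float, float]
    mean_difference: float
    pearson_r: float | None
    n: int
    paired: bool

    def summary(self) -> str:
        r = "n/a" if self.pearson_r is None else f"{self.pearson_r:.3f}"
        return (
            "Bulk qPCR vs single-cell concordance\n"
            f"  bulk residual: {self.bulk_mean:.3f} "
            f"[{self.bulk_ci[0]:.3f}, {self.bulk_ci[1]:.3f}]\n"
            f"  single-cell residual: {self.sc_mean:.3f} "
            f"[{self.sc_ci[0]:.3f}, {self.sc_ci[1]:.3f}]\n"
            f"  mean difference (sc - bulk): {self.mean_difference:.3f}  "
            f"pearson r: {r}  n: {self.n}"
        )


def _t_ci(x, conf=0.95):
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if x.size < 2:
        return m, (np.nan, np.nan)
    sem = x.std(ddof=1) / np.sqrt(x.size)
    tq = stats.t.ppf(0.5 + conf / 2.0, df=x.size - 1)
    return m, (m - tq * sem, m + tq * sem)


def concordance_stats(bulk_residuals, sc_residuals, paired: bool = True) -> Concordance:
    """Compare residual fractions measured by bulk qPCR and by aggregated
    single-cell sequencing (crosshair means with 95% t CIs, paired mean
    difference, Pearson correlation when n >= 3)."""
    bulk = np.asarray(bulk_residuals, dtype=float)
    sc = np.asarray(sc_residuals, dtype=float)
    if paired and bulk.size != sc.size:
        warnings.warn("unpaired inputs; falling back to group-level comparison")
        paired = False
    bm, bci = _t_ci(bulk)
    sm, sci = _t_ci(sc)
    diff = float(np.mean(sc - bulk)) if paired else float(sm - bm)
    r = None
    if paired and bulk.size >= 3 and np.std(bulk) > 0 and np.std(sc) > 0:
        r = float(np.corrcoef(bulk, sc)[0, 1])
    return Concordance(
        bulk_mean=float(bm), bulk_ci=(float(bci[0]), float(bci[1])),
        sc_mean=float(sm), sc_ci=(float(sci[0]), float(sci[1])),
        mean_difference=diff, pearson_r=r, n=int(min(bulk.size, sc.size)),
        paired=paired,
    )
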