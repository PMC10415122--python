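"""Comparison of knockdown profiles across cell types, conditions and species.

Cell types differ enormously in abundance, so all summary statistics here are
cell-count weighted: weighted Pearson correlations for testing candidate
covariates and for comparing profiles between datasets, and weighted standard
deviations for quantifying between-cell-type variability of target
engagement.  Weights are normalized to sum to the number of observations, so
with equal weights every statistic reduces exactly to its unweighted form and
p-values use the ordinary t reference with n - 2 degrees of freedom (the
convention of the R helpers ``weights::wtd.cor`` / ``Hmisc::wtd.var``).

Public outputs are expressed in percent of vehicle control; washout/recovery
is the rise of residual target between two timepoints in percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23


def _normalized_weights(w, n):
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    return w * n / w.sum()


def weighted_pearson(x, y, w) -> tuple[float, float]:
    """Weighted Pearson correlation and two-sided p-value.

    The correlation comes from weighted (co)variances; the p-value from a t
    statistic with weights normalized to sum to n, i.e. n - 2 effective
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if y.size != n or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite and of equal length")
    w = _normalized_weights(w, n)
    mx = np.sum(w * x) / n
    my = np.sum(w * y) / n
    vx = np.sum(w * (x - mx) ** 2) / (n - 1)
    vy = np.sum(w * (y - my) ** 2) / (n - 1)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance; correlation undefined")
    cov = np.sum(w * (x - mx) * (y - my)) / (n - 1)
    rho = float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def weighted_sd(x, w, frequency: bool = False) -> float:
    """Square root of the weighted unbiased variance.

    By default weights are normalized to sum to n (so equal weights of any
    magnitude reduce exactly to the ordinary sample SD).  With
    ``frequency=True`` weights are treated as integer repeat counts and the
    result equals the SD of the weight-expanded sample — the two conventions
    of ``Hmisc::wtd.var`` (normwt TRUE/FALSE), which coincide for unit
    weights.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if frequency:
        w = np.asarray(w, dtype=float)
        if np.any(w < 0) or w.sum() <= 1:
            raise ValueError("frequency weights must be non-negative and sum above 1")
        m = np.sum(w * x) / w.sum()
        return float(np.sqrt(np.sum(w * (x - m) ** 2) / (w.sum() - 1)))
    w = _normalized_weights(w, n)
    m = np.sum(w * x) / n
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / (n - 1)))


def diff_from_overall(residuals: pd.Series, overall_residual: float) -> pd.Series:
    """Each cell type's residual minus the overall residual, percentage points.

    ``residuals`` is indexed by cell type, in percent of control; the overall
    residual is the estimate from aggregating all cells regardless of cell
    type.  With cell-count weights and a pooled overall, the weighted mean of
    the differences is approximately zero.
    """
    residuals = pd.Series(residuals, dtype=float)
    return residuals - float(overall_residual)


@dataclass
class WashoutRecord:
    """Recovery of residual target between two timepoints for one cell type."""

    cell_type: str
    residual_t1: float
    residual_t2: float

    @property
    def recovery(self) -> float:
        return self.residual_t2 - self.residual_t1


def washout_recovery(est_t1, est_t2) -> pd.DataFrame:
    """Percentage points of recovery (t2 minus t1 residual) per cell type.

    Inputs are mappings/Series of residual target in percent of control at an
    early (t1) and late (t2) timepoint.  Cell types are inner-joined; drops
    are warned about.
    """
    s1 = pd.Series(est_t1, dtype=float)
    s2 = pd.Series(est_t2, dtype=float)
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise ValueError("no shared cell types between the two timepoints")
    dropped = sorted(set(s1.index).symmetric_difference(s2.index))
    if dropped:
        warnings.warn(f"cell types present at only one timepoint dropped: {dropped}")
    out = pd.DataFrame({
        "cell_type": shared,
        "residual_t1": s1[shared].to_numpy(),
        "residual_t2": s2[shared].to_numpy(),
    })
    out["recovery"] = out["residual_t2"] - out["residual_t1"]
    return out


@dataclass
class DoseArithmetic:
    """Molecule-count bookkeeping for a bolus ASO dose."""

    molecules_total: float
    molecules_per_cell: float
    productive_per_cell: float

    @staticmethod
    def _round_sig(x: float, sig: int = 1) -> float:
        if x == 0:
            return 0.0
        return float(round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))

    @property
    def molecules_total_1sf(self) -> float:
        return self._round_sig(self.molecules_total)

    @property
    def molecules_per_cell_1sf(self) -> float:
        return self._round_sig(self.molecules_per_cell)


def dose_molecule_count(dose_mass: float, molecular_weight: float, n_cells: float,
                        productive_fraction: float = 1.0) -> DoseArithmetic:
    """How many ASO molecules a dose contains, per brain cell.

    ``dose_mass`` in grams, ``molecular_weight`` in g/mol.  A 50 ug dose of a
    ~7 kDa oligonucleotide is ~4e15 molecules; spread over ~1e8 brain cells
    that exceeds 1e7 molecules per cell, of which ``productive_fraction``
    undergo productive uptake.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    if dose_mass <= 0 or n_cells <= 0:
        raise ValueError("dose_mass and n_cells must be positive")
    if not 0.0 <= productive_fraction <= 1.0:
        raise ValueError("productive_fraction must be in [0, 1]")
    total = AVOGADRO * dose_mass / molecular_weight
    per_cell = total / n_cells
    return DoseArithmetic(
        molecules_total=total,
        molecules_per_cell=per_cell,
        productive_per_cell=per_cell * productive_fraction,
    )


def correlogram(profiles: dict[str, pd.Series], weights: dict[str, pd.Series],
                combine: str = "sum") -> pd.DataFrame:
    """Weighted correlations between every pair of datasets.

    ``profiles`` maps dataset name -> residuals (percent) indexed by cell
    type; ``weights`` maps dataset name -> cell counts per cell type.  For
    each pair, cell types are inner-joined and per-cell-type weights combined
    by ``sum`` (total cells across the two datasets) or ``min``.
    """
    if combine not in ("sum", "min"):
        raise ValueError("combine must be 'sum' or 'min'")
    names = sorted(profiles)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = profiles[a].index.intersection(profiles[b].index)
            if len(shared) < 3:
                warnings.warn(f"skipping pair ({a}, {b}): fewer than 3 shared cell types")
                continue
            wa = pd.Series(weights[a], dtype=float)[shared]
            wb = pd.Series(weights[b], dtype=float)[shared]
            w = wa + wb if combine == "sum" else np.minimum(wa, wb)
            rho, p = weighted_pearson(profiles[a][shared], profiles[b][shared], w)
            rows.append({"dataset_a": a, "dataset_b": b, "rho": rho, "p": p,
                         "n_celltypes": len(shared)})
    return pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "rho", "p", "n_celltypes"])
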