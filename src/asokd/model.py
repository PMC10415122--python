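"""Pseudobulk NB-GLM estimation of per-cell-type residual target RNA.

Cells are grouped by (animal, cell type) and their target/total UMIs summed;
the aggregate counts are modelled as

    target_umi ~ NB(mean = exp(b_ct + b_ct:trt * 1[treated] + log(total_umi)),
                    size = theta)

i.e. a negative-binomial GLM with one baseline log-rate per cell type, one
treatment interaction per cell type, and the log total UMIs as exposure
offset.  ``exp(b_ct:trt)`` is the mean residual target RNA fraction in that
cell type under treatment; 95% confidence intervals are
``exp(b +/- 1.96 * SE)``.  Per-animal point estimates are the animal's
observed target rate divided by the fitted vehicle rate of its cell type
(equivalently, the link-scale model residual added to the interaction
coefficient and exponentiated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountData, align_counts_to_metadata, validate_metadata
from .errors import SchemaError
from .nbglm import NBGLMFit, fit_nb_glm_design

AGG_COLUMNS = ["animal", "cell_type", "arm", "target_umi", "total_umi", "n_cells"]


def aggregate_counts(counts: CountData, meta: pd.DataFrame) -> pd.DataFrame:
    """Sum target and total UMIs by (animal, cell type).

    Returns one row per observed (animal, cell_type) pair with exact integer
    sums, the arm label, and the number of cells.  Cell types absent from one
    arm are flagged with a warning (their treatment effect is inestimable).
    """
    if len(meta) == 0:
        warnings.warn("empty input: no cells to aggregate")
        return pd.DataFrame(columns=AGG_COLUMNS)
    validate_metadata(meta)
    counts = align_counts_to_metadata(counts, meta)
    df = meta[["animal", "cell_type", "arm"]].copy()
    df["target_umi"] = counts.target_umi
    df["total_umi"] = counts.total_umi
    agg = (
        df.groupby(["animal", "cell_type", "arm"], sort=True, observed=True)
        .agg(target_umi=("target_umi", "sum"), total_umi=("total_umi", "sum"),
             n_cells=("target_umi", "size"))
        .reset_index()[AGG_COLUMNS]
    )
    arms_per_ct = agg.groupby("cell_type")["arm"].agg(lambda s: frozenset(s))
    lopsided = sorted(arms_per_ct.index[arms_per_ct != frozenset({"vehicle", "treated"})])
    if lopsided:
        warnings.warn(f"cell types present in only one arm: {lopsided}")
    return agg


@dataclass
class KnockdownEstimate:
    """Residual target RNA in one cell type, as fractions of vehicle."""

    cell_type: str
    residual_mean: float
    ci_low: float
    ci_high: float
    per_animal: dict[str, float]
    n_cells_vehicle: int
    n_cells_treated: int


class KnockdownModel:
    """NB pseudobulk model of residual target RNA per cell type.

    Parameters
    ----------
    agg : DataFrame
        Aggregate table with columns animal, cell_type, arm, target_umi,
        total_umi, n_cells (see :func:`aggregate_counts`).  Cell types with
        zero target counts in both arms are dropped with a warning.
    """

    def __init__(self, agg: pd.DataFrame):
        missing = [c for c in AGG_COLUMNS[:5] if c not in agg.columns]
        if missing:
            raise SchemaError(f"aggregate table missing columns: {missing}")
        agg = agg.copy()
        if "n_cells" not in agg.columns:
            agg["n_cells"] = np.nan
        if (agg["total_umi"] <= 0).any():
            raise ValueError("total_umi must be positive in every aggregate row")
        arms = set(agg["arm"])
        if not {"vehicle", "treated"} <= arms:
            raise ValueError(f"need both vehicle and treated rows, got arms {sorted(arms)}")
        for arm in ("vehicle", "treated"):
            n_animals = agg.loc[agg["arm"] == arm, "animal"].nunique()
            if n_animals < 2:
                warnings.warn(f"only {n_animals} {arm} animal(s); estimates will be fragile")

        dead = (
            agg.groupby("cell_type")["target_umi"].sum().pipe(lambda s: s.index[s == 0])
        )
        if len(dead):
            warnings.warn(f"dropping cell types with zero target counts in both arms: "
                          f"{sorted(dead)}")
            agg = agg[~agg["cell_type"].isin(dead)]
        self.agg = agg.reset_index(drop=True)

        self.cell_types = sorted(self.agg["cell_type"].unique())
        treated_cts = set(self.agg.loc[self.agg["arm"] == "treated", "cell_type"])
        skipped = [ct for ct in self.cell_types if ct not in treated_cts]
        if skipped:
            warnings.warn(f"cell types missing from the treated arm are omitted from "
                          f"interaction terms: {skipped}")
        self.interaction_cts = [ct for ct in self.cell_types if ct in treated_cts]

    def _design(self):
        agg = self.agg
        n = len(agg)
        k, m = len(self.cell_types), len(self.interaction_cts)
        X = np.zeros((n, k + m))
        ct_idx = {ct: j for j, ct in enumerate(self.cell_types)}
        int_idx = {ct: k + j for j, ct in enumerate(self.interaction_cts)}
        treated = (agg["arm"] == "treated").to_numpy()
        for i, ct in enumerate(agg["cell_type"]):
            X[i, ct_idx[ct]] = 1.0
            if treated[i] and ct in int_idx:
                X[i, int_idx[ct]] = 1.0
        names = ([f"celltype[{ct}]" for ct in self.cell_types]
                 + [f"celltype[{ct}]:treated" for ct in self.interaction_cts])
        return X, names

    def fit(self, theta: float | None = None, z: float = 1.96) -> "KnockdownResults":
        """Maximize the NB likelihood (profiling theta unless given) and
        package per-cell-type estimates."""
        X, names = self._design()
        y = self.agg["target_umi"].to_numpy(dtype=float)
        offset = np.log(self.agg["total_umi"].to_numpy(dtype=float))
        fit = fit_nb_glm_design(y, X, offset, theta=theta)
        return KnockdownResults(self, fit, names, z=z)


class KnockdownResults:
    """Fitted pseudobulk knockdown model.

    Attributes
    ----------
    params : Series
        All coefficients on the natural-log scale.
    bse : Series
        Wald standard errors.
    theta : float
        Fitted NB size parameter.
    """

    def __init__(self, model: KnockdownModel, fit: NBGLMFit, names: list[str],
                 z: float = 1.96):
        self.model = model
        self._fit = fit
        self.z = z
        self.params = pd.Series(fit.beta, index=names)
        self.bse = pd.Series(fit.se, index=names)
        self.theta = fit.theta
        self.llf = fit.loglik
        self.converged = fit.converged
        self.n_iter = fit.n_iter

    # -- coefficient access -------------------------------------------------
    def baseline_rate(self, cell_type: str) -> float:
        """Fitted vehicle target rate (target UMIs per total UMI)."""
        return float(np.exp(self.params[f"celltype[{cell_type}]"]))

    def interaction(self, cell_type: str) -> tuple[float, float]:
        """(coefficient, SE) of the treatment interaction, log scale."""
        key = f"celltype[{cell_type}]:treated"
        return float(self.params[key]), float(self.bse[key])

    def conf_int(self) -> pd.DataFrame:
        lo = self.params - self.z * self.bse
        hi = self.params + self.z * self.bse
        return pd.DataFrame({"low": lo, "high": hi})

    # -- knockdown estimates ------------------------------------------------
    @property
    def estimates(self) -> pd.DataFrame:
        """Per-cell-type residual fractions with CIs and cell counts."""
        agg = self.model.agg
        ncells = agg.pivot_table(index="cell_type", columns="arm", values="n_cells",
                                 aggfunc="sum", fill_value=0)
        rows = []
        for ct in self.model.interaction_cts:
            b, se = self.interaction(ct)
            rows.append({
                "cell_type": ct,
                "n_cells_vehicle": int(ncells.loc[ct].get("vehicle", 0)),
                "n_cells_treated": int(ncells.loc[ct].get("treated", 0)),
                "residual_mean": np.exp(b),
                "ci_low": np.exp(b - self.z * se),
                "ci_high": np.exp(b + self.z * se),
            })
        return pd.DataFrame(rows)

    @property
    def per_animal(self) -> pd.DataFrame:
        """Per-animal residual points: observed rate / fitted vehicle rate.

        Emitted for both arms (vehicle points reproduce the control scatter
        around 1).  Animals with zero target UMIs get point estimate 0.
        """
        agg = self.model.agg
        rows = []
        for _, r in agg.iterrows():
            ct = r["cell_type"]
            if ct not in self.model.interaction_cts and r["arm"] == "treated":
                continue
            rate = r["target_umi"] / r["total_umi"]
            rows.append({
                "cell_type": ct, "animal": r["animal"], "arm": r["arm"],
                "n_cells": r["n_cells"],
                "point": rate / self.baseline_rate(ct),
            })
        return pd.DataFrame(rows)

    def knockdown_estimates(self) -> list[KnockdownEstimate]:
        per = self.per_animal
        out = []
        for _, e in self.estimates.iterrows():
            ct = e["cell_type"]
            pa = per[(per["cell_type"] == ct) & (per["arm"] == "treated")]
            out.append(KnockdownEstimate(
                cell_type=ct,
                residual_mean=float(e["residual_mean"]),
                ci_low=float(e["ci_low"]), ci_high=float(e["ci_high"]),
                per_animal=dict(zip(pa["animal"], pa["point"])),
                n_cells_vehicle=int(e["n_cells_vehicle"]),
                n_cells_treated=int(e["n_cells_treated"]),
            ))
        return out

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Pseudobulk NB knockdown model",
            f"  rows: {len(self.model.agg)}  cell types: {len(self.model.cell_types)}",
            f"  theta: {self.theta:.4g}  loglik: {self.llf:.4f}  "
            f"converged: {self.converged} ({self.n_iter} iter)",
            "",
            f"  {'cell_type':<20}{'residual':>10}{'ci_low':>10}{'ci_high':>10}"
            f"{'n_veh':>8}{'n_trt':>8}",
        ]
        for _, e in est.iterrows():
            lines.append(
                f"  {e['cell_type']:<20}{e['residual_mean']:>10.4f}"
                f"{e['ci_low']:>10.4f}{e['ci_high']:>10.4f}"
                f"{e['n_cells_vehicle']:>8d}{e['n_cells_treated']:>8d}"
            )
        return "\n".join(lines)


# -- functional surface ------------------------------------------------------

def fit_nb_glm(rows: pd.DataFrame, theta: float | None = None) -> KnockdownResults:
    """Fit the pseudobulk NB GLM to an aggregate table."""
    return KnockdownModel(rows).fit(theta=theta)


def estimate_knockdown(fit: KnockdownResults,
                       rows: pd.DataFrame | None = None) -> list[KnockdownEstimate]:
    """Per-cell-type residual estimates from a fitted model."""
    return fit.knockdown_estimates()
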