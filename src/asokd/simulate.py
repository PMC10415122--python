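"""Synthetic single-nucleus UMI count experiments.

Generates per-cell target and total UMI counts with the statistical structure
the downstream analysis assumes: several cell types with unequal proportions,
heavy-tailed per-cell library sizes, cell-type-specific basal target
expression on the UMIs-per-million (UPM) scale, animal-level rate
variability, replicate animals per treatment arm, and — for the treated arm —
one of two competing single-cell knockdown mechanisms:

``scale``
    uniform mean scaling: every cell's NB mean is multiplied by the residual
    fraction ``r`` (equal knockdown in all cells);
``zero``
    all-or-none silencing: a fraction ``1 - r`` of cells is set to zero
    target counts, the rest keep the control distribution.

Both mechanisms conserve the expected target count ``r * mu`` per cell, so
pseudobulk estimates cannot tell them apart; their per-cell count
distributions can.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nb import nb_rvs
from .data import CountData

MECHANISMS = ("scale", "zero")

#: Minimum total UMIs per cell; droplet QC pipelines discard smaller cells.
MIN_TOTAL_UMI = 100


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    Parameters
    ----------
    name : str
    proportion : float
        Expected fraction of cells of this type, in [0, 1].
    basal_upm : float
        Basal target expression in UMIs per million total UMIs (UPM) in
        vehicle-treated animals.
    """

    name: str
    proportion: float
    basal_upm: float


@dataclass
class SimConfig:
    """Full description of one synthetic knockdown experiment.

    Defaults reflect a typical single-nucleus cohort: 4 animals per arm,
    ~7650 total UMIs per cell (log-normal, sdlog 0.5), NB overdispersion
    theta = 10, and mild animal-level variability (sdlog 0.1) of the target
    rate.
    """

    cell_types: list[CellTypeSpec]
    residual: dict[str, float]
    mechanism: str = "scale"
    theta: float = 10.0
    totals_meanlog: float = math.log(7650.0)
    totals_sdlog: float = 0.5
    animal_sdlog: float = 0.1
    n_animals_per_arm: int = 4
    n_cells_per_animal: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        props = np.array([ct.proportion for ct in self.cell_types], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions must sum to 1, got {props.sum()!r}")
        if np.any(props < 0):
            raise ValueError("cell type proportions must be non-negative")
        for ct in self.cell_types:
            if not np.isfinite(ct.basal_upm) or ct.basal_upm < 0:
                raise ValueError(f"basal_upm must be finite and >= 0 for {ct.name!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        missing = [ct.name for ct in self.cell_types if ct.name not in self.residual]
        if missing:
            raise ValueError(f"residual fraction missing for cell types: {missing}")
        for name, r in self.residual.items():
            if r < 0:
                raise ValueError(f"residual must be >= 0, got {r} for {name!r}")
            if self.mechanism == "zero" and r > 1:
                raise ValueError(
                    f"mechanism='zero' requires residual <= 1, got {r} for {name!r}"
                )
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError("theta must be finite and > 0")
        if not (np.isfinite(self.totals_meanlog) and np.isfinite(self.totals_sdlog)):
            raise ValueError("totals parameters must be finite")
        if self.totals_sdlog < 0 or self.animal_sdlog < 0:
            raise ValueError("sdlog parameters must be >= 0")
        if self.n_animals_per_arm < 1 or self.n_cells_per_animal < 1:
            raise ValueError("need at least one animal per arm and one cell per animal")


def reference_config(r: float = 0.5, mechanism: str = "scale", seed: int = 0,
                     basal_upm: float = 300.0, **overrides) -> SimConfig:
    """Single-cell-type design used throughout for parameter recovery."""
    return SimConfig(
        cell_types=[CellTypeSpec("neuron", 1.0, basal_upm)],
        residual={"neuron": r},
        mechanism=mechanism,
        seed=seed,
        **overrides,
    )


def sample_cell_totals(n: int, totals_meanlog: float, totals_sdlog: float,
                       rng) -> np.ndarray:
    """Draw per-cell total UMI counts: log-normal, rounded, floored at 100."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if totals_sdlog < 0:
        raise ValueError("totals_sdlog must be >= 0")
    rng = np.random.default_rng(rng)
    raw = rng.lognormal(mean=totals_meanlog, sigma=totals_sdlog, size=n)
    return np.maximum(np.rint(raw).astype(np.int64), MIN_TOTAL_UMI)


def sample_target_counts(totals, basal_upm: float, residual: float, mechanism: str,
                         theta: float, rng) -> np.ndarray:
    """Draw per-cell target UMI counts under the given knockdown mechanism.

    Control (vehicle) cells are the special case ``residual = 1``, for which
    both mechanisms reduce to a plain NB draw with mean
    ``mu_i = basal_upm * total_i / 1e6``.  Counts are capped at the cell's
    total so target <= total always holds (the cap binds with negligible
    probability at realistic UPM).
    """
    if residual < 0:
        raise ValueError("residual must be >= 0")
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}")
    if mechanism == "zero" and residual > 1:
        raise ValueError("mechanism='zero' requires residual <= 1")
    rng = np.random.default_rng(rng)
    totals = np.asarray(totals, dtype=np.int64)
    mu = basal_upm * totals / 1e6
    if mechanism == "scale":
        counts = nb_rvs(residual * mu, theta, rng)
    else:
        # NB draw first so residual=1 reproduces the control draw exactly
        counts = nb_rvs(mu, theta, rng)
        keep = rng.random(totals.size) < residual
        counts[~keep] = 0
    return np.minimum(counts, totals)


def simulate_experiment(config: SimConfig) -> tuple[CountData, pd.DataFrame]:
    """Simulate a full treated-vs-vehicle cohort.

    Returns per-cell counts plus a metadata table (barcode, animal, arm,
    cell_type).  Each animal carries a log-normal(0, ``animal_sdlog``)
    multiplicative factor on its target rate (not on totals), giving the
    pseudobulk GLM real animal-level residuals.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = [ct.name for ct in config.cell_types]
    props = np.array([ct.proportion for ct in config.cell_types])
    basal = {ct.name: ct.basal_upm for ct in config.cell_types}

    frames, targets, totals_all = [], [], []
    for arm in ("vehicle", "treated"):
        for a in range(config.n_animals_per_arm):
            animal = f"{arm[0]}{a + 1}"
            n = config.n_cells_per_animal
            factor = rng.lognormal(0.0, config.animal_sdlog) if config.animal_sdlog > 0 else 1.0
            cts = rng.choice(len(names), size=n, p=props)
            totals = sample_cell_totals(n, config.totals_meanlog, config.totals_sdlog, rng)
            target = np.zeros(n, dtype=np.int64)
            for j, name in enumerate(names):
                mask = cts == j
                if not mask.any():
                    continue
                r = 1.0 if arm == "vehicle" else config.residual[name]
                target[mask] = sample_target_counts(
                    totals[mask], basal[name] * factor, r, config.mechanism,
                    config.theta, rng,
                )
            frames.append(pd.DataFrame({
                "barcode": [f"{animal}-{i:05d}" for i in range(n)],
                "animal": animal,
                "arm": arm,
                "cell_type": [names[j] for j in cts],
            }))
            targets.append(target)
            totals_all.append(totals)

    meta = pd.concat(frames, ignore_index=True)
    counts = CountData(
        target_umi=np.concatenate(targets),
        total_umi=np.concatenate(totals_all),
        barcodes=list(meta["barcode"]),
    )
    return counts, meta


def expand_to_matrix(counts: CountData, n_background_genes: int = 9,
                     target_name: str = "Target", rng=None):
    """Spread each cell's non-target UMIs over background genes.

    Produces a small cells x genes integer matrix whose row sums equal the
    simulated totals exactly (gene 0 is the target; the remainder is split
    multinomially over ``n_background_genes`` synthetic filler genes), for
    exercising 10x-style matrix I/O round-trips.
    """
    from scipy import sparse

    rng = np.random.default_rng(rng)
    rest = counts.total_umi - counts.target_umi
    p = np.full(n_background_genes, 1.0 / n_background_genes)
    bg = rng.multinomial(rest, p)  # (n_cells, n_background_genes)
    dense = np.column_stack([counts.target_umi, bg])
    features = pd.DataFrame({
        "feature_id": [f"GENE{i:04d}" for i in range(n_background_genes + 1)],
        "symbol": [target_name] + [f"Bg{i}" for i in range(n_background_genes)],
    })
    return sparse.csr_matrix(dense), features
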