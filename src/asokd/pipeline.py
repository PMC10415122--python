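"""End-to-end orchestration: counts -> aggregate -> fit -> mechanism -> outputs.

``run_pipeline`` ties the stages together and writes TSV results plus a JSON
manifest (inputs, seed, thresholds, package version) sufficient to reproduce
a run byte-identically.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .data import ARMS
from .errors import AsokdError
from .mechanism import DEFAULT_THRESHOLD, MechanismModel
from .model import KnockdownModel, aggregate_counts
from .tenx import read_counts_10x, read_metadata

log = logging.getLogger("asokd")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    counts_path: str
    metadata_path: str
    target_gene: str
    output_dir: str
    qpcr_path: str | None = None
    arms: tuple[str, str] = ARMS
    seed: int = 0
    mechanism_threshold: float = DEFAULT_THRESHOLD
    z: float = 1.96

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AsokdError:
                raise
            except Exception as exc:
                raise AsokdError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write outputs; returns the manifest."""
    os.makedirs(config.output_dir, exist_ok=True)

    log.info("reading counts from %s", config.counts_path)
    tenx = read_counts_10x(config.counts_path)
    tenx.gene_index(config.target_gene)  # fail early on absent/ambiguous gene
    meta = read_metadata(config.metadata_path, arms=config.arms)
    counts = tenx.extract(config.target_gene)

    log.info("aggregating %d cells", len(meta))
    agg = _stage("aggregate")(aggregate_counts)(counts, meta)
    agg_path = os.path.join(config.output_dir, "aggregate.tsv")
    agg.to_csv(agg_path, sep="\t", index=False)

    log.info("fitting NB pseudobulk model")
    res = _stage("fit")(lambda: KnockdownModel(agg).fit(z=config.z))()
    est_path = os.path.join(config.output_dir, "estimates.tsv")
    res.estimates.to_csv(est_path, sep="\t", index=False)
    pa_path = os.path.join(config.output_dir, "per_animal.tsv")
    res.per_animal.to_csv(pa_path, sep="\t", index=False)

    log.info("mechanism discrimination per cell type")
    mech_rows = []
    from .data import align_counts_to_metadata

    counts = align_counts_to_metadata(counts, meta)
    arm = meta["arm"].to_numpy()
    for ct in res.model.interaction_cts:
        m = (meta["cell_type"] == ct).to_numpy()
        ctrl = counts.target_umi[m & (arm == "vehicle")]
        trt = counts.target_umi[m & (arm == "treated")]
        if ctrl.size == 0 or trt.size == 0 or ctrl.sum() == 0:
            log.warning("skipping mechanism test for %s (insufficient data)", ct)
            continue
        r = _stage("mechanism")(MechanismModel(ctrl, trt).fit)(
            threshold=config.mechanism_threshold)
        mech_rows.append({
            "cell_type": ct, "n_control": r.control.n_cells, "n_treated": r.n_treated,
            "mu": r.control.mu, "theta": r.control.theta, "r_hat": r.r_hat,
            "loglik_scale": r.loglik_scale, "loglik_zero": r.loglik_zero,
            "delta": r.delta, "verdict": r.verdict,
        })
    mech_path = os.path.join(config.output_dir, "mechanism.tsv")
    pd.DataFrame(mech_rows, columns=["cell_type", "n_control", "n_treated", "mu",
                                     "theta", "r_hat", "loglik_scale", "loglik_zero",
                                     "delta", "verdict"]).to_csv(mech_path, sep="\t",
                                                                 index=False)

    outputs = {"aggregate": agg_path, "estimates": est_path,
               "per_animal": pa_path, "mechanism": mech_path}

    if config.qpcr_path:
        from .qpcr import concordance_stats, delta_delta_ct

        log.info("qPCR reduction from %s", config.qpcr_path)
        records = pd.read_csv(config.qpcr_path, sep="\t")
        ddct = _stage("qpcr")(delta_delta_ct)(records)
        qpcr_path = os.path.join(config.output_dir, "qpcr_residuals.tsv")
        ddct.to_csv(qpcr_path, sep="\t", index=False)
        outputs["qpcr_residuals"] = qpcr_path

        treated = ddct[ddct["group"] == "treated"].sort_values("sample")
        sc_points = (res.per_animal[res.per_animal["arm"] == "treated"]
                     .groupby("animal")
                     .apply(lambda g: np.average(g["point"], weights=g["n_cells"]),
                            include_groups=False)
                     .sort_index())
        if len(treated) == len(sc_points) and len(treated) > 0:
            conc = concordance_stats(treated["residual"].to_numpy(),
                                     sc_points.to_numpy())
            conc_path = os.path.join(config.output_dir, "concordance.txt")
            with open(conc_path, "w") as fh:
                fh.write(conc.summary() + "\n")
            outputs["concordance"] = conc_path

    manifest = {
        "asokd_version": __version__,
        "config": {**asdict(config), "arms": list(config.arms)},
        "thresholds": {"mechanism_delta": config.mechanism_threshold, "ci_z": config.z},
        "seed": config.seed,
        "n_cells": int(len(meta)),
        "outputs": outputs,
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
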