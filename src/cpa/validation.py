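"""Synthetic-scenario validation of the full pipeline.

Runs the default synthetic scenario end-to-end and measures the properties
that make the method trustworthy: null-threshold calibration on fresh
permutations, family-wise-error control of the cluster-extent rule, and
recovery/dissociability of the planted misconfiguration types.  Used by
the test suite and the result-reproduction script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import nullmodel
from .metrics import METRICS
from .pipeline import (AnalysisConfig, _group_sizes, load_significance_masks,
                       load_thresholds, load_zmaps, run_synthetic_demo)
from .synthdata import GroundTruth, evaluate_recovery

#: which metric is designed to detect which planted effect
MATCHED_METRIC = {"gain": "aggregate_divergence",
                  "rank_permutation": "rank_misarrangement",
                  "concentration": "entropy_shift"}


def validate_default_scenario(workdir: str | Path, seed: int = 0,
                              n_perm: int = 200, n_fresh: int = 1000,
                              n_fwe: int = 200) -> dict:
    """Generate, analyse and validate the default synthetic scenario.

    Returns a dict with keys:

    ``config``, ``truth``        the analysis config and ground truth
    ``thresholds``               per-metric voxel/extent thresholds
    ``calibration``              per-metric dict from
                                 :func:`cpa.nullmodel.calibration_check`
    ``fwe``                      per-metric family-wise error rate of the
                                 cluster rule on fresh null permutations,
                                 with its binomial SE
    ``recovery``                 :func:`cpa.synthdata.evaluate_recovery`
                                 table for all metric/comparison masks
    """
    config, truth = run_synthetic_demo(
        workdir, seed=seed, n_perm=n_perm,
        stages=("fingerprints", "null", "groupmaps", "clusters"))
    thresholds = load_thresholds(config, "validation")
    zn, _ = load_zmaps(config, "normative", "validation")
    n_a, n_b = _group_sizes(config, "validation")
    grid = zn[0].grid
    structure = nullmodel.connectivity_structure(config.connectivity)

    calibration, fwe = {}, {}
    for i, metric in enumerate(METRICS):
        # same seed as the pipeline's null stage, so the threshold the
        # bootstrap perturbs is the one actually applied downstream
        build = nullmodel.null_metric_samples(
            zn, metric, n_a, n_b, n_perm, seed=config.seed + i)
        fresh = nullmodel.null_metric_samples(
            zn, metric, n_a, n_b, n_fresh, seed=config.seed + 7000 + i)
        check = nullmodel.calibration_check(build, fresh, config.alpha,
                                            seed=config.seed + 11)
        assert check["threshold"] == thresholds[metric]["voxel_threshold"]
        calibration[metric] = check

        fwe_samples = nullmodel.null_metric_samples(
            zn, metric, n_a, n_b, n_fwe, seed=config.seed + 8000 + i)
        k_thr = thresholds[metric]["k_threshold"]
        survived = 0
        for p in range(n_fwe):
            vol = grid.embed(fwe_samples[p]
                             >= thresholds[metric]["voxel_threshold"]) > 0
            if nullmodel.max_cluster_size(vol, structure) >= k_thr:
                survived += 1
        fwe[metric] = {
            "rate": survived / n_fwe,
            "se": float(np.sqrt(config.alpha_fwe * (1 - config.alpha_fwe)
                                / n_fwe)),
            "n": n_fwe,
        }

    masks = load_significance_masks(config, "validation")
    recovery = evaluate_recovery(masks, truth)
    return {"config": config, "truth": truth, "thresholds": thresholds,
            "calibration": calibration, "fwe": fwe, "recovery": recovery}


def recovery_summary(recovery: pd.DataFrame) -> dict:
    """Matched sensitivities and worst-case cross-metric detection.

    Matched sensitivity is taken in the comparison where the effect is
    expected (the abstinent comparison for abstinent-only effects; both
    comparisons for trait effects).  Cross-metric detection is the
    detection of a planted region by a *non*-matching metric, maximised
    over regions and comparisons.
    """
    out: dict[str, float] = {}
    cross_max = 0.0
    for _, row in recovery.iterrows():
        effect, metric = row["effect"], row["metric"]
        comp = ("abstinent" if "abstinent" in row["comparison"] else "sated")
        key = f"{effect}__{metric}__{comp}"
        out[key] = row["sensitivity_pct"]
        matched = MATCHED_METRIC[effect] == metric
        expected_here = (row["effect_state"] == "trait"
                         or comp == "abstinent")
        if not matched:
            cross_max = max(cross_max, row["sensitivity_pct"])
        elif matched and expected_here:
            out.setdefault(f"matched__{effect}__{comp}",
                           row["sensitivity_pct"])
    out["cross_metric_max"] = cross_max
    return out
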