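"""Brain-behaviour regression: misconfiguration magnitude vs severity scores.

Subject-level misconfiguration magnitudes (cluster-mean metric values) are
related to dependence severity and withdrawal symptomology by ordinary
least squares with demographic covariates.  The interaction model regresses
the outcome on {intercept, AD, ROM, AD x ROM, age, sex, education}, with
the interaction computed after mean-centring AD and ROM so its coefficient
is interpretable at average misconfiguration levels (the highest-order
term's t statistic is unaffected by the centring).  Sex is coded 0/1
(male = 0); subjects with any missing outcome or predictor are dropped
listwise; p-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .inference import SubjectMetricMap


@dataclass
class RegressionResult:
    """OLS summary: one row per term."""

    table: pd.DataFrame       # term, coef, se, t, p
    residual_df: int
    n_used: int
    r_squared: float

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def extract_cluster_means(subject_maps: list[SubjectMetricMap],
                          mask: np.ndarray) -> np.ndarray:
    """Mean metric value over the mask voxels, one scalar per subject."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cluster mask")
    out = []
    for m in subject_maps:
        if m.values.shape != mask.shape:
            raise ValueError("mask not aligned to subject map grid")
        out.append(float(m.values[mask].mean()))
    return np.array(out)


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        arr = design.to_numpy()
        for j, col in enumerate(design.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(str(col))
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    if len(y) <= design.shape[1]:
        raise ValueError("more terms than observations")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame({
        "term": design.columns,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return RegressionResult(table=table, residual_df=int(fit.df_resid),
                            n_used=int(fit.nobs),
                            r_squared=float(fit.rsquared))


def _clean(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.dropna(axis=0, how="any")


def interaction_regression(outcome: np.ndarray, ad: np.ndarray,
                           rom: np.ndarray, age: np.ndarray, sex: np.ndarray,
                           education: np.ndarray) -> RegressionResult:
    """OLS of outcome on AD, ROM, their (centred) interaction and covariates.

    ``sex`` may be 0/1 numeric or "male"/"female" strings.
    """
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex = (sex == "female").astype(float)
    frame = pd.DataFrame({
        "outcome": np.asarray(outcome, dtype=float),
        "ad": np.asarray(ad, dtype=float),
        "rom": np.asarray(rom, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "education": np.asarray(education, dtype=float),
    })
    frame = _clean(frame)
    ad_c = frame["ad"] - frame["ad"].mean()
    rom_c = frame["rom"] - frame["rom"].mean()
    X = pd.DataFrame({
        "ad": ad_c, "rom": rom_c, "ad_x_rom": ad_c * rom_c,
        "age": frame["age"], "sex": frame["sex"],
        "education": frame["education"],
    })
    return _fit_ols(frame["outcome"].to_numpy(), X)


def withdrawal_regression(outcome: np.ndarray, predictor: np.ndarray,
                          age: np.ndarray, sex: np.ndarray,
                          education: np.ndarray) -> RegressionResult:
    """OLS of a withdrawal score on one misconfiguration magnitude plus
    age, sex and education (no interaction term)."""
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex = (sex == "female").astype(float)
    frame = pd.DataFrame({
        "outcome": np.asarray(outcome, dtype=float),
        "predictor": np.asarray(predictor, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "education": np.asarray(education, dtype=float),
    })
    frame = _clean(frame)
    X = frame[["predictor", "age", "sex", "education"]]
    return _fit_ols(frame["outcome"].to_numpy(), X)


def save_regression(result: RegressionResult, csv_path: str,
                    json_path: str | None = None,
                    spec: dict | None = None) -> None:
    """Persist a RegressionResult as CSV (+ JSON sidecar echoing the model
    specification for provenance)."""
    result.table.to_csv(csv_path, index=False)
    if json_path is not None:
        import json
        meta = {"residual_df": result.residual_df, "n_used": result.n_used,
                "r_squared": result.r_squared}
        if spec:
            meta["model"] = spec
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)
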