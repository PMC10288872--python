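"""Normative analysis of callosal parcel areas.

A reference linear model (sex, age, total cortical surface) is fitted on
controls only; every subject's residue (observed minus predicted area)
is compared with the control 10th percentile, and the excess of flagged
subjects in each patient group is tested with Fisher's exact test,
BH-corrected across the eight surfaces (total CC + 7 parcels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import SURFACES, ccps_column
from .stats import TestResult, bh_fdr, fisher_exact, ols

#: Control residue quantile used as the abnormality threshold (percent).
DEFAULT_PERCENTILE = 10.0

_COVARIATES = ("SEX", "AGE", "TCxS", "const")


@dataclass
class NormativeModel:
    """Control-fitted reference model for one surface."""

    surface: str
    coef: dict[str, float]
    control_residues: np.ndarray
    threshold: float
    percentile: float
    n_controls: int

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _covariate_matrix(df)
        b = np.array([self.coef[c] for c in _COVARIATES])
        return X @ b


def _covariate_matrix(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        df["sex"].to_numpy(float),
        df["age_years"].to_numpy(float),
        df["tcxs_cm2"].to_numpy(float),
        np.ones(len(df)),
    ])


def control_quantile(x: np.ndarray, percentile: float,
                     method: str = "linear") -> float:
    """Empirical quantile, linear interpolation on order statistics.

    The default convention is q(p) = x_(1+(n-1)p) on the ascending sort
    (so residues 1..10 give a 10th percentile of 1.9).
    """
    x = np.asarray(x, dtype=float)
    return float(np.quantile(x, percentile / 100.0, method=method))


def fit_normative(df: pd.DataFrame, surface: str,
                  percentile: float = DEFAULT_PERCENTILE,
                  quantile_method: str = "linear") -> NormativeModel:
    """Fit the control-only reference model for one surface."""
    if surface not in SURFACES:
        raise ValidationError(f"unknown surface {surface!r}")
    controls = df[df["group"] == "control"]
    if len(controls) < 10:
        raise ValidationError("need >= 10 controls to fit the normative model")
    X = _covariate_matrix(controls)
    y = controls[ccps_column(surface)].to_numpy(float)
    beta, _, resid, _, _ = ols(X, y, list(_COVARIATES))
    threshold = control_quantile(resid, percentile, quantile_method)
    return NormativeModel(
        surface=surface,
        coef={c: float(b) for c, b in zip(_COVARIATES, beta)},
        control_residues=resid,
        threshold=threshold,
        percentile=percentile,
        n_controls=len(controls),
    )


def apply_normative(model: NormativeModel, df: pd.DataFrame) -> pd.DataFrame:
    """Residue and below-threshold flag for every subject, one surface.

    The flag is strict (residue < threshold).  A zero area (agenesis)
    simply yields a large negative residue and is flagged like any
    other value.
    """
    observed = df[ccps_column(model.surface)].to_numpy(float)
    residue = observed - model.predict(df)
    return pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy(),
        "group": df["group"].to_numpy(),
        "surface": model.surface,
        "residue": residue,
        "below": residue < model.threshold,
    })


def excess_test(flags: pd.DataFrame, group: str) -> pd.DataFrame:
    """Fisher test of flag excess in one patient group vs controls.

    ``flags`` must hold rows for several surfaces (from
    :func:`apply_normative`); BH runs across the surfaces present.
    """
    out = []
    for surface, sub in flags.groupby("surface", sort=False):
        pat = sub[sub["group"] == group]
        ctl = sub[sub["group"] == "control"]
        if len(pat) == 0 or len(ctl) == 0:
            raise ValidationError(f"missing {group} or control rows for {surface}")
        a = int(pat["below"].sum())
        b = len(pat) - a
        c = int(ctl["below"].sum())
        d = len(ctl) - c
        res: TestResult = fisher_exact(a, b, c, d)
        out.append({"surface": surface, "group": group,
                    "n_below": a, "n_group": len(pat),
                    "n_below_control": c, "n_control": len(ctl),
                    "p": res.p})
    table = pd.DataFrame(out)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table


def run_normative(df: pd.DataFrame, patient_groups: tuple[str, ...] = ("FAS", "NS-FASD"),
                  percentile: float = DEFAULT_PERCENTILE,
                  quantile_method: str = "linear"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full normative pass over all surfaces and patient groups.

    Returns (per-subject flags, per-group summary with p and q).
    """
    flag_frames = []
    for surface in SURFACES:
        model = fit_normative(df, surface, percentile, quantile_method)
        flag_frames.append(apply_normative(model, df))
    flags = pd.concat(flag_frames, ignore_index=True)
    summaries = [excess_test(flags, g)
                 for g in patient_groups if (df["group"] == g).any()]
    summary = pd.concat(summaries, ignore_index=True) if summaries \
        else pd.DataFrame()
    return flags, summary
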