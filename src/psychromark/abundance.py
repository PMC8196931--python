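"""Regression and ANCOVA over-representation tests across metagenomes.

Per-sample counts of group-specific hits are regressed on pan-genome hits
(which absorb the shared sampling-depth signal); a one-way ANCOVA (k = 2)
then asks whether a cohort of samples sits on a different line.  The
ANCOVA first tests homogeneity of slopes via the interaction term; only
when slopes are parallel (p >= 0.05) is the intercept (adjusted-mean)
comparison valid.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from psychromark.types import AncovaResult, RegressionFit, SampleMetadata

#: MAT cutpoints (degC) standing in for the polar/temperate/tropical split
MAT_PA_MAX = 0.0
MAT_TEMPERATE_MAX = 18.0

_TAG_MAP = {
    "pa": "PA",
    "polar": "PA",
    "alpine": "PA",
    "temperate": "temperate",
    "tropical": "tropical",
}


def classify_climate(
    meta: SampleMetadata,
    pa_max: float = MAT_PA_MAX,
    temperate_max: float = MAT_TEMPERATE_MAX,
) -> str:
    """PA / temperate / tropical from an explicit tag, else from MAT.

    MAT < 0 degC -> PA; 0 <= MAT < 18 -> temperate; MAT >= 18 -> tropical.
    Samples with neither tag nor MAT are 'unassigned' and excluded from
    cohort tests.
    """
    tag = (meta.climate or "").strip().lower()
    if tag in _TAG_MAP:
        return _TAG_MAP[tag]
    if meta.mat is None:
        return "unassigned"
    if meta.mat < pa_max:
        return "PA"
    if meta.mat < temperate_max:
        return "temperate"
    return "tropical"


def fit_group_regression(
    hits: pd.DataFrame, group: str, pan_col: str = "hits_pan"
) -> RegressionFit:
    """OLS of ``hits_<group>`` on pan-genome hits across samples."""
    ycol = f"hits_{group}"
    if ycol not in hits.columns or pan_col not in hits.columns:
        raise KeyError(f"hit table must contain {ycol!r} and {pan_col!r}")
    x = hits[pan_col].to_numpy(dtype=float)
    y = hits[ycol].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples for a reported fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in pan-genome hits")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(x),
    )


def ancova_two_cohorts(
    hits: pd.DataFrame,
    cohorts: pd.Series,
    group: str = "C",
    pan_col: str = "hits_pan",
    slope_alpha: float = 0.05,
) -> AncovaResult:
    """One-way ANCOVA (k = 2) comparing the two cohorts' regression lines.

    Step 1: F-test of the cohort x covariate interaction (slope
    homogeneity).  Step 2: if slopes are homogeneous, F-test of the
    cohort effect in the common-slope model (equivalently a comparison of
    adjusted means / y-intercepts).  ``valid`` is False when slopes
    differ, in which case intercepts are not compared.
    """
    cohorts = cohorts.loc[hits.index]
    levels = sorted(cohorts.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two cohorts required, got {levels}")
    ycol = f"hits_{group}"
    x = hits[pan_col].to_numpy(dtype=float)
    y = hits[ycol].to_numpy(dtype=float)
    z = (cohorts == levels[1]).to_numpy(dtype=float)
    for lv in levels:
        sel = cohorts == lv
        if sel.sum() < 3:
            raise ValueError(f"cohort {lv!r} has fewer than 3 samples")
        if np.ptp(x[sel.to_numpy()]) == 0:
            raise ValueError(f"degenerate covariate in cohort {lv!r}")

    x_c = x - x.mean()
    full = sm.OLS(y, sm.add_constant(np.column_stack([x_c, z, x_c * z]))).fit()
    reduced = sm.OLS(y, sm.add_constant(np.column_stack([x_c, z]))).fit()
    slope_p = float(full.compare_f_test(reduced)[1])

    covariate_only = sm.OLS(y, sm.add_constant(x_c)).fit()
    intercept_p = float(reduced.compare_f_test(covariate_only)[1])

    b = reduced.params  # [const, x_c, z]
    adjusted = {levels[0]: float(b[0]), levels[1]: float(b[0] + b[2])}

    valid = slope_p >= slope_alpha
    return AncovaResult(
        slope_homogeneity_p=slope_p,
        intercept_diff_p=intercept_p if valid else None,
        adjusted_means=adjusted,
        valid=valid,
    )
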