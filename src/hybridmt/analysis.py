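"""Downstream analyses: apparent-parameter maps, phantom GLM, cohort stats.

These are the operations applied to fitted parameter maps: voxel-wise
conversion to the *apparent* parameters an ``R1s = R1f``-constrained model
would report, the generalized-linear-model fit of phantom tube medians
against protein concentration and field strength, case-control comparison of
per-subject median ROI values, and the two-column PCA used to quantify how
much independent information two parameters carry across lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from .mt_model import TissueParameters, taylor_apparent

__all__ = [
    "GLMResult",
    "apparent_maps",
    "glm_fit",
    "glm_predict",
    "cohort_compare",
    "lesion_pca",
]


@dataclass
class GLMResult:
    """OLS fit of ``a0 + a_bsa*c + a_b0*B0 + a2*c*B0`` with 95% CIs."""

    coefficients: np.ndarray  # (a0, a_bsa, a_b0, a2)
    conf_int: np.ndarray  # (4, 2) lower/upper 95% bounds
    r_squared: float

    @property
    def a0(self) -> float:
        return float(self.coefficients[0])

    @property
    def a_bsa(self) -> float:
        return float(self.coefficients[1])

    @property
    def a_b0(self) -> float:
        return float(self.coefficients[2])

    @property
    def a2(self) -> float:
        return float(self.coefficients[3])


def apparent_maps(
    m0s: np.ndarray,
    r1f: np.ndarray,
    r1s: np.ndarray,
    rx: np.ndarray,
    order: int = 2,
) -> dict[str, np.ndarray]:
    """Voxel-wise apparent parameters from unconstrained parameter maps.

    Applies the Taylor-expanded constrained-model conversion
    (:func:`hybridmt.mt_model.taylor_apparent`) to every finite voxel; NaN
    voxels (outside the mask) propagate.  Returns maps ``m0s_a``, ``r1f_a``
    and ``rx_a``.
    """
    arrs = [np.asarray(a, dtype=float) for a in (m0s, r1f, r1s, rx)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("input maps must share one shape")
    m0s, r1f, r1s, rx = arrs
    out = {
        k: np.full(m0s.shape, np.nan) for k in ("m0s_a", "r1f_a", "rx_a")
    }
    valid = np.isfinite(m0s) & np.isfinite(r1f) & np.isfinite(r1s) & np.isfinite(rx)
    for idx in np.argwhere(valid):
        idx = tuple(idx)
        tis = TissueParameters(
            m0s=float(m0s[idx]),
            R1f=float(r1f[idx]),
            R2f=1.0,
            Rx=float(rx[idx]),
            R1s=float(r1s[idx]),
            T2s=10e-6,
        )
        r1f_a, rx_a, m0s_a = taylor_apparent(tis, order=order)
        out["r1f_a"][idx] = r1f_a
        out["rx_a"][idx] = rx_a
        out["m0s_a"][idx] = m0s_a
    return out


def glm_fit(values, c_bsa, b0) -> GLMResult:
    """OLS fit of tube medians on ``[1, c, B0, c*B0]`` with t-based 95% CIs.

    ``values`` are per-tube median parameter estimates, ``c_bsa`` the
    protein mass fractions and ``b0`` the field strengths (T), all equal
    length with at least 5 observations.
    """
    y = np.asarray(values, dtype=float)
    c = np.asarray(c_bsa, dtype=float)
    b = np.asarray(b0, dtype=float)
    if not y.shape == c.shape == b.shape:
        raise ValueError("values, c_bsa and b0 must have equal shapes")
    if y.size < 5:
        raise ValueError("need at least 5 observations")
    X = np.column_stack([np.ones_like(c), c, b, c * b])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("design matrix is rank deficient")
    model = sm.OLS(y, X).fit()
    return GLMResult(
        coefficients=np.asarray(model.params),
        conf_int=np.asarray(model.conf_int(alpha=0.05)),
        r_squared=float(model.rsquared),
    )


def glm_predict(coefficients, c_bsa, b0):
    """Evaluate the GLM surface ``a0 + a_bsa*c + a_b0*B0 + a2*c*B0``."""
    a0, a_bsa, a_b0, a2 = coefficients
    c = np.asarray(c_bsa, dtype=float)
    b = np.asarray(b0, dtype=float)
    return a0 + a_bsa * c + a_b0 * b + a2 * c * b


def cohort_compare(
    table: pd.DataFrame,
    parameter: str,
    roi: str,
    group_col: str = "group",
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[float, float]:
    """Case-control difference of per-subject median ROI values.

    ``table`` has one row per subject x ROI with columns ``subject``,
    ``roi``, ``group`` and one column per parameter (the subject's median
    over the ROI).  Returns ``(effect, p_value)`` where the effect is
    ``mean(case medians) - mean(control medians)`` and the p-value comes
    from a two-sided exact Wilcoxon rank-sum (Mann-Whitney U) test on the
    per-subject medians.
    """
    sub = table[table["roi"] == roi]
    cases = sub.loc[sub[group_col] == case_label, parameter].to_numpy(float)
    controls = sub.loc[sub[group_col] == control_label, parameter].to_numpy(
        float
    )
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = float(np.mean(cases) - np.mean(controls))
    _, p = mannwhitneyu(cases, controls, alternative="two-sided", method="exact")
    return effect, float(p)


def lesion_pca(values: np.ndarray) -> np.ndarray:
    """Explained-variance fractions of a two-column lesion table.

    Standardizes each column (the two parameters have different units),
    then returns the eigenvalues of the 2x2 correlation matrix normalized
    to fractions summing to 1, sorted descending.  For two standardized
    columns with correlation rho the first fraction is ``(1 + |rho|)/2``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("values must be an (n_lesions, 2) table")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 lesions")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    corr = np.corrcoef(x, rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return ev / ev.sum()
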