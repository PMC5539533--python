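"""Index-versus-cellulose regression: linear and quadratic OLS fits, R²,
and a nested-model F test comparing the two.

Cellulose content (% of fiber mass, Updegraff-type assay output) is the
response y; the spectral response (index or PC1 score) is the predictor x.
R² of a simple linear fit is orientation-invariant; the quadratic fit is not,
so the orientation matters and is fixed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "RegressionFit",
    "ModelComparison",
    "ols_polyfit",
    "compare_linear_quadratic",
    "correlate_indices",
]

#: spectral responses reported by correlate_indices, in output order
RESPONSES = ["r_value", "ci_ir", "ratio_1372_2900", "area_895", "area_664"]


@dataclass(frozen=True)
class RegressionFit:
    """OLS polynomial fit of y on x.

    coefficients are intercept-first: y_hat = c0 + c1 x (+ c2 x²).
    r_squared = 1 - residual_ss/total_ss, reported as 0 (with a warning) when
    y is constant.
    """

    degree: int
    coefficients: np.ndarray
    r_squared: float
    n: int
    residual_ss: float
    total_ss: float

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


@dataclass(frozen=True)
class ModelComparison:
    """Linear vs quadratic nested comparison on the same data."""

    linear: RegressionFit
    quadratic: RegressionFit
    delta_r_squared: float
    f_statistic: float
    p_value: float


def ols_polyfit(x, y, degree: int) -> RegressionFit:
    """Ordinary least squares on the polynomial design of the given degree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape}, {y.shape}")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}, got {n}")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("all x values equal; design matrix is singular")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise np.linalg.LinAlgError("rank-deficient polynomial design")
    resid = y - design @ coef
    residual_ss = float(resid @ resid)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss > 0:
        r2 = 1.0 - residual_ss / total_ss
    else:
        warnings.warn("constant response: R² reported as 0", stacklevel=2)
        r2 = 0.0
    return RegressionFit(
        degree=degree,
        coefficients=coef,
        r_squared=r2,
        n=n,
        residual_ss=residual_ss,
        total_ss=total_ss,
    )


def compare_linear_quadratic(x, y) -> ModelComparison:
    """Fit both degrees and test the quadratic term with a nested F test.

    F = (SSres1 - SSres2) / (SSres2 / (n - 3)) on F(1, n-3).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("model comparison needs >=5 points")
    lin = ols_polyfit(x, y, 1)
    quad = ols_polyfit(x, y, 2)
    n = lin.n
    delta_ss = lin.residual_ss - quad.residual_ss
    denom = quad.residual_ss / (n - 3)
    if denom <= 0:  # perfect quadratic fit
        f_stat = np.inf if delta_ss > 0 else 0.0
        p = 0.0 if delta_ss > 0 else 1.0
    else:
        f_stat = (delta_ss / 1.0) / denom
        p = float(f_dist.sf(f_stat, 1, n - 3))
    return ModelComparison(
        linear=lin,
        quadratic=quad,
        delta_r_squared=quad.r_squared - lin.r_squared,
        f_statistic=float(f_stat),
        p_value=p,
    )


def correlate_indices(
    indices: pd.DataFrame,
    cellulose: pd.Series,
    scores: pd.DataFrame | None = None,
    by_genotype: bool = False,
) -> pd.DataFrame:
    """Regress cellulose content on each spectral response.

    One row per response (the four indices, the band-ratio, and PC1 when a
    score table is supplied) with linear R², quadratic R², their difference,
    and the nested-F p-value.  Pooled across genotypes by default;
    ``by_genotype=True`` adds per-genotype rows.
    """
    frame = indices.copy()
    if scores is not None:
        if "pc1_score" not in scores.columns:
            raise ValueError("scores table lacks a pc1_score column")
        frame = frame.merge(scores[["sample_id", "pc1_score"]], on="sample_id")
    missing = sorted(set(frame["sample_id"]) - set(cellulose.index))
    if missing:
        raise KeyError(f"samples without cellulose values: {missing}")
    frame["cellulose_pct"] = frame["sample_id"].map(cellulose).astype(float)

    responses = RESPONSES + (["pc1_score"] if scores is not None else [])
    groups = [("all", frame)]
    if by_genotype:
        groups += [(g, sub) for g, sub in frame.groupby("genotype", sort=True)]

    rows = []
    for label, sub in groups:
        y = sub["cellulose_pct"].to_numpy()
        for resp in responses:
            cmp_ = compare_linear_quadratic(sub[resp].to_numpy(), y)
            rows.append(
                {
                    "response": resp,
                    "genotype": label,
                    "n": cmp_.linear.n,
                    "linear_r2": cmp_.linear.r_squared,
                    "quadratic_r2": cmp_.quadratic.r_squared,
                    "delta_r2": cmp_.delta_r_squared,
                    "f_statistic": cmp_.f_statistic,
                    "f_p_value": cmp_.p_value,
                }
            )
    return pd.DataFrame(rows)
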