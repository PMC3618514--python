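"""GLM association of topology and anisotropy with autistic traits.

Each response (a cost-integrated nodal metric, a global efficiency, or a
regional FA value; one observation per subject) is regressed on the trait
scores plus covariates with ordinary least squares:

- design 1: intercept + ASSQ + SRS + age + gender
- design 2: design 1 + verbal IQ

The trait effect is a joint F-contrast on the (ASSQ, SRS) coefficients
(2 df by default; a 1-df contrast on the combined standardized score is
available).  Effect sizes are partial eta squared,
eta_p^2 = F*dfh / (F*dfh + dfe), reported for the contrast and for every
individual slope.  Families of regional p-values are corrected with the
Benjamini-Hochberg step-up FDR procedure at alpha = 0.05.

Gender is coded 0 = female, 1 = male.  With a single observation per
subject and region, a subject-level random effect is unidentifiable and is
absorbed into the residual (plain OLS per region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GLMDesign",
    "SlopeResult",
    "AssociationResult",
    "design_matrix",
    "fit_glm",
    "partial_eta_squared",
    "bh_fdr",
    "run_regional_association",
]


@dataclass
class GLMDesign:
    """Predictor set and trait contrast for one GLM family.

    ``design_id`` 1 uses age and gender as covariates; 2 additionally
    controls verbal IQ.  ``traits`` are the trait terms under test; with
    ``combined_score=True`` they are replaced by one standardized combined
    score (1-df contrast).
    """

    design_id: int = 1
    traits: tuple[str, ...] = ("assq", "srs")
    combined_score: bool = False

    def __post_init__(self) -> None:
        if self.design_id not in (1, 2):
            raise ValueError("design_id must be 1 or 2")
        if not self.traits:
            raise ValueError("at least one trait term is required")

    @property
    def trait_terms(self) -> tuple[str, ...]:
        return ("trait_combined",) if self.combined_score else self.traits

    @property
    def predictors(self) -> tuple[str, ...]:
        covs = ("age", "gender") if self.design_id == 1 else ("age", "gender", "verbal_iq")
        return ("intercept",) + self.trait_terms + covs

    def contrast(self) -> np.ndarray:
        """Contrast matrix selecting the trait terms (one row per df)."""
        p = self.predictors
        c = np.zeros((len(self.trait_terms), len(p)))
        for row, term in enumerate(self.trait_terms):
            c[row, p.index(term)] = 1.0
        return c


@dataclass
class SlopeResult:
    """Single-predictor slope with its own F-test and effect size."""

    b: float
    f: float
    p: float
    partial_eta_sq: float


@dataclass
class AssociationResult:
    """Per-region (or global) GLM output."""

    region: str
    f_stat: float
    p_value: float
    partial_eta_sq: float
    slopes: dict[str, SlopeResult]
    dfh: int
    dfe: int
    fdr_significant: bool | None = field(default=None)


def design_matrix(phenotypes: pd.DataFrame, design: GLMDesign) -> np.ndarray:
    """Numeric design matrix in ``design.predictors`` column order."""
    n = len(phenotypes)
    cols = []
    for term in design.predictors:
        if term == "intercept":
            cols.append(np.ones(n))
        elif term == "gender":
            g = phenotypes["gender"]
            if g.dtype == object or str(g.dtype) == "category":
                cols.append((g == "male").to_numpy(dtype=float))
            else:
                cols.append(g.to_numpy(dtype=float))
        elif term == "trait_combined":
            z_a = stats.zscore(phenotypes["assq"].to_numpy(dtype=float), ddof=1)
            z_s = stats.zscore(phenotypes["srs"].to_numpy(dtype=float), ddof=1)
            cols.append(stats.zscore((z_a + z_s) / 2.0, ddof=1))
        else:
            cols.append(phenotypes[term].to_numpy(dtype=float))
    x = np.column_stack(cols)
    if np.isnan(x).any():
        raise ValueError("design matrix contains missing values")
    return x


def partial_eta_squared(f: float, dfh: int, dfe: int) -> float:
    """Effect size eta_p^2 = F*dfh / (F*dfh + dfe)."""
    if f < 0 or dfh < 1 or dfe < 1:
        raise ValueError("need f >= 0, dfh >= 1, dfe >= 1")
    if np.isinf(f):
        return 1.0
    return (f * dfh) / (f * dfh + dfe)


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level alpha.

    Rejects every p <= p_(k*), where k* is the largest k with
    p_(k) <= (k/m) * alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * alpha
    if not below.any():
        return np.zeros(m, dtype=bool)
    k_star = np.max(np.flatnonzero(below))
    reject = np.zeros(m, dtype=bool)
    reject[order[: k_star + 1]] = True
    return reject


def _vectorized_ols(x: np.ndarray, y: np.ndarray, contrast: np.ndarray):
    """OLS of many responses on one design; joint contrast and slope tests.

    ``y`` is (n, r).  Returns (beta, f_con, p_con, f_slopes, p_slopes, dfe)
    with beta (p, r), slope arrays (p, r).
    """
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dfe = n - p
    if dfe < 1:
        raise ValueError("more predictors than observations")
    s2 = (resid**2).sum(axis=0) / dfe

    cb = contrast @ beta                       # (q, r)
    m = contrast @ xtx_inv @ contrast.T        # (q, q)
    q = contrast.shape[0]
    quad = (cb * np.linalg.solve(m, cb)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_con = np.where(s2 > 0, quad / q / s2, np.inf)
    p_con = stats.f.sf(f_con, q, dfe)

    se2 = np.outer(np.diag(xtx_inv), s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_slopes = np.where(se2 > 0, beta**2 / se2, np.inf)
    p_slopes = stats.f.sf(f_slopes, 1, dfe)
    return beta, f_con, p_con, f_slopes, p_slopes, dfe


def fit_glm(response, phenotypes: pd.DataFrame, design: GLMDesign,
            region: str = "global") -> AssociationResult:
    """Single-response GLM fit (statsmodels OLS) with the trait F-contrast."""
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    x = design_matrix(phenotypes, design)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, x).fit()
    ct = fit.f_test(design.contrast())
    dfh = int(ct.df_num)
    dfe = int(fit.df_resid)
    f_stat = float(ct.fvalue)
    slopes = {}
    for j, term in enumerate(design.predictors):
        fj = float(fit.tvalues[j] ** 2)
        slopes[term] = SlopeResult(
            b=float(fit.params[j]),
            f=fj,
            p=float(fit.pvalues[j]),
            partial_eta_sq=partial_eta_squared(fj, 1, dfe),
        )
    return AssociationResult(
        region=region,
        f_stat=f_stat,
        p_value=float(ct.pvalue),
        partial_eta_sq=partial_eta_squared(f_stat, dfh, dfe),
        slopes=slopes,
        dfh=dfh,
        dfe=dfe,
    )


def run_regional_association(
    metrics,
    phenotypes: pd.DataFrame,
    design: GLMDesign | None = None,
    alpha: float = 0.05,
    region_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region GLM family with BH-FDR correction across regions.

    ``metrics`` is subjects x regions (DataFrame or array) aligned with the
    phenotype rows.  Returns one row per region: the joint trait contrast
    (f, p, partial_eta_sq), per-predictor slopes (b_/f_/p_/eta_ columns),
    and the FDR flag computed across this family's p-values.
    """
    design = design or GLMDesign()
    if isinstance(metrics, pd.DataFrame):
        names = region_names or [str(c) for c in metrics.columns]
        y = metrics.to_numpy(dtype=float)
    else:
        y = np.asarray(metrics, dtype=float)
        names = region_names or [f"region {i}" for i in range(y.shape[1])]
    if y.shape[0] != len(phenotypes):
        raise ValueError("metrics rows must align with phenotype rows")
    if np.isnan(y).any():
        raise ValueError("metrics contain missing values")
    x = design_matrix(phenotypes, design)
    contrast = design.contrast()
    beta, f_con, p_con, f_sl, p_sl, dfe = _vectorized_ols(x, y, contrast)
    dfh = contrast.shape[0]

    out = {
        "region": names,
        "f": f_con,
        "p": p_con,
        "partial_eta_sq": [partial_eta_squared(f, dfh, dfe) for f in f_con],
        "dfh": dfh,
        "dfe": dfe,
    }
    for j, term in enumerate(design.predictors):
        if term == "intercept":
            continue
        out[f"b_{term}"] = beta[j]
        out[f"f_{term}"] = f_sl[j]
        out[f"p_{term}"] = p_sl[j]
        out[f"eta_{term}"] = [partial_eta_squared(f, 1, dfe) for f in f_sl[j]]
    frame = pd.DataFrame(out)
    frame["fdr_significant"] = bh_fdr(frame["p"].to_numpy(), alpha=alpha)
    return frame
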