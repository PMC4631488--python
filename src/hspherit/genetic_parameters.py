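"""Derived quantitative-genetic quantities.

From fitted (or externally supplied) variance components this module computes
narrow-sense heritability h2 = V_A / V_P, repeatability
R = (V_A + V_C + V_PE) / V_P, the mean-standardised coefficients of variation

    CV_A = 100 * sqrt(V_A) / mean,      CV_R = 100 * sqrt(V_P - V_A) / mean,

the truncation-selection intensity i = phi(z)/p, and the predicted
per-generation response to selection G = i * h2 * sigma_P (breeder's
equation), also expressed as a percentage of the trait mean.

Standard errors of the ratios use the first-order delta method on the
variance-component covariance (inverse average-information) matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixed_model import ModelFit, VarianceComponents

__all__ = [
    "components_from_values",
    "heritability",
    "repeatability",
    "cv_additive",
    "cv_residual",
    "selection_intensity",
    "predicted_response",
    "SelectionScenario",
    "GeneticParameters",
    "summarize_fit",
    "parameter_table",
]

_BETWEEN_ROLES = ("additive", "common_env", "permanent_env")


def components_from_values(
    v_additive: float,
    v_residual: float,
    *,
    v_common_env: float = 0.0,
    v_permanent_env: float = 0.0,
    varcov: np.ndarray | None = None,
) -> VarianceComponents:
    """Assemble a :class:`VarianceComponents` from plain numbers.

    Useful for recomputing derived statistics from published tables, where
    only the component point estimates (and not a fit) are available.
    """
    names, vals, roles = ["additive"], [v_additive], {"additive": "additive"}
    if v_common_env:
        names.append("family")
        vals.append(v_common_env)
        roles["family"] = "common_env"
    if v_permanent_env:
        names.append("pe")
        vals.append(v_permanent_env)
        roles["pe"] = "permanent_env"
    names.append("residual")
    vals.append(v_residual)
    roles["residual"] = "residual"
    k = len(names)
    vc = np.zeros((k, k)) if varcov is None else np.asarray(varcov, dtype=float)
    return VarianceComponents(
        names=tuple(names),
        estimates=dict(zip(names, map(float, vals))),
        se={nm: float(np.sqrt(vc[i, i])) for i, nm in enumerate(names)},
        boundary={nm: False for nm in names},
        roles=roles,
        varcov=vc,
    )


def _ratio_with_se(
    components: VarianceComponents, numerator_roles: tuple[str, ...]
) -> tuple[float, float]:
    vp = components.V_P
    if vp <= 0:
        raise ValueError("total phenotypic variance must be positive")
    num = components.by_role(*numerator_roles)
    ratio = num / vp
    # delta method: d(num/vp)/d theta_k = (1[k in num] * vp - num) / vp^2
    grad = np.array(
        [
            ((vp if components.roles[nm] in numerator_roles else 0.0) - num) / vp**2
            for nm in components.names
        ]
    )
    var = float(grad @ components.varcov @ grad)
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def heritability(components: VarianceComponents) -> tuple[float, float]:
    """Narrow-sense heritability h2 = V_A / V_P and its delta-method SE."""
    return _ratio_with_se(components, ("additive",))


def repeatability(components: VarianceComponents) -> tuple[float, float]:
    """Repeatability R = (V_A + V_C + V_PE) / V_P and its delta-method SE.

    R pools all permanent between-individual variance and is therefore an
    upper bound for h2 whenever all components are non-negative.
    """
    return _ratio_with_se(components, _BETWEEN_ROLES)


def cv_additive(v_additive: float, mean: float) -> float:
    """Coefficient of additive genetic variation, percent of the trait mean."""
    if mean <= 0:
        raise ValueError("CV is undefined for a non-positive mean")
    if v_additive < 0:
        raise ValueError("additive variance must be non-negative")
    return 100.0 * math.sqrt(v_additive) / mean


def cv_residual(v_phenotypic: float, v_additive: float, mean: float) -> float:
    """Residual coefficient of variation, 100*sqrt(V_P - V_A)/mean.

    The non-additive remainder V_P - V_A (not the residual component alone)
    is used, so CV_A^2 + CV_R^2 = (100*sigma_P/mean)^2 holds exactly.
    """
    if mean <= 0:
        raise ValueError("CV is undefined for a non-positive mean")
    if v_phenotypic < v_additive:
        raise ValueError("phenotypic variance smaller than additive variance")
    return 100.0 * math.sqrt(v_phenotypic - v_additive) / mean


def selection_intensity(p: float) -> float:
    """Selection intensity i = phi(z)/p for truncation at the upper-p tail.

    Mean phenotypic superiority of the selected fraction, in phenotypic SD
    units, under normality.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must lie in (0, 1)")
    z = sps.norm.isf(p)
    return float(sps.norm.pdf(z) / p)


@dataclass(frozen=True)
class SelectionScenario:
    """One truncation-selection scenario evaluated with the breeder's equation."""

    proportion: float
    intensity: float
    h2: float
    sigma_P: float
    mean: float
    response: float
    response_percent: float


def predicted_response(
    p: float, h2: float, sigma_P: float, mean: float
) -> SelectionScenario:
    """Predicted per-generation response G = i * h2 * sigma_P.

    ``response_percent`` expresses G as a percentage of the trait mean.
    """
    if not np.isfinite([p, h2, sigma_P, mean]).all():
        raise ValueError("inputs must be finite")
    if mean <= 0:
        raise ValueError("mean must be positive for the percent form")
    i = selection_intensity(p)
    g = i * h2 * sigma_P
    return SelectionScenario(
        proportion=p,
        intensity=i,
        h2=h2,
        sigma_P=sigma_P,
        mean=mean,
        response=g,
        response_percent=100.0 * g / mean,
    )


@dataclass(frozen=True)
class GeneticParameters:
    """One row of a genetic-parameter report (one trait x stratum x model)."""

    trait: str
    stratum: str
    model: str
    n_obs: int
    mean: float
    sd: float
    V_A: float
    V_A_se: float
    V_C: float
    V_PE: float
    V_R: float
    V_R_se: float
    V_P: float
    V_P_se: float
    h2: float
    h2_se: float
    R: float | None
    R_se: float | None
    CV_A: float
    CV_R: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "stratum": self.stratum,
            "model": self.model,
            "n": self.n_obs,
            "mean": self.mean,
            "sd": self.sd,
            "V_A": self.V_A,
            "V_A_se": self.V_A_se,
            "V_C": self.V_C,
            "V_PE": self.V_PE,
            "V_R": self.V_R,
            "V_R_se": self.V_R_se,
            "V_P": self.V_P,
            "V_P_se": self.V_P_se,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "R": self.R,
            "R_se": self.R_se,
            "CV_A": self.CV_A,
            "CV_R": self.CV_R,
            "converged": self.converged,
        }


def _se_by_role(comps: VarianceComponents, role: str) -> float:
    return float(
        sum(comps.se[nm] for nm in comps.names if comps.roles[nm] == role)
    )


def summarize_fit(
    fit: ModelFit,
    *,
    trait: str,
    stratum: str,
    model: str,
    include_repeatability: bool = False,
) -> GeneticParameters:
    """Derive the report row (h2, CVs, optionally R) from a converged fit."""
    comps = fit.components
    vp = comps.V_P
    h2, h2_se = heritability(comps)
    if include_repeatability:
        r, r_se = repeatability(comps)
    else:
        r, r_se = None, None
    mean = float(np.mean(fit.design.y))
    sd = float(np.std(fit.design.y, ddof=1))
    ones = np.ones(len(comps.names))
    vp_se = float(np.sqrt(max(ones @ comps.varcov @ ones, 0.0)))
    return GeneticParameters(
        trait=trait,
        stratum=stratum,
        model=model,
        n_obs=fit.n_obs,
        mean=mean,
        sd=sd,
        V_A=comps.V_A,
        V_A_se=_se_by_role(comps, "additive"),
        V_C=comps.by_role("common_env"),
        V_PE=comps.by_role("permanent_env"),
        V_R=comps.V_R,
        V_R_se=_se_by_role(comps, "residual"),
        V_P=vp,
        V_P_se=vp_se,
        h2=h2,
        h2_se=h2_se,
        R=r,
        R_se=r_se,
        CV_A=cv_additive(comps.V_A, mean) if mean > 0 else float("nan"),
        CV_R=cv_residual(vp, comps.V_A, mean) if mean > 0 else float("nan"),
        converged=fit.converged,
    )


def parameter_table(rows: list[GeneticParameters]) -> pd.DataFrame:
    """Stack report rows into the table layout used for publication tables.

    Full numeric precision is retained; round at presentation time only.
    An empty input yields an empty table with the header in place.
    """
    cols = [
        "trait",
        "stratum",
        "model",
        "n",
        "mean",
        "sd",
        "V_A",
        "V_A_se",
        "V_C",
        "V_PE",
        "V_R",
        "V_R_se",
        "V_P",
        "V_P_se",
        "h2",
        "h2_se",
        "R",
        "R_se",
        "CV_A",
        "CV_R",
        "converged",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.as_dict() for r in rows], columns=cols)
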