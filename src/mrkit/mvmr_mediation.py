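"""Multivariable MR (direct effects conditional on co-exposures) and
difference-method mediation decomposition with proportion mediated."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import Z95, MRResult


class RankDeficiencyError(ValueError):
    """Exposure effect matrix is rank-deficient (collinear exposures)."""


@dataclass
class MVMRInput:
    """Per-SNP effects on k exposures and one outcome, pre-harmonized.

    ``beta_x`` and ``se_x`` are (J, k) arrays aligned with ``snps``;
    ``beta_y``/``se_y`` are length-J vectors on the same effect alleles.
    """

    snps: list
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    exposure_names: list

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.snps) > 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, k = self.beta_x.shape
        if k < 1:
            raise ValueError("need at least one exposure")
        if len(self.exposure_names) != k:
            raise ValueError("exposure_names length must equal k")
        if j < k + 1:
            raise ValueError("need at least k + 1 SNPs")
        if self.se_x.shape != (j, k) or self.beta_y.shape != (j,) or self.se_y.shape != (j,):
            raise ValueError("inconsistent array shapes")
        if not (self.se_x > 0).all() or not (self.se_y > 0).all():
            raise ValueError("standard errors must be positive")

    @property
    def k(self) -> int:
        return self.beta_x.shape[1]


def mvmr(inp: MVMRInput, effects: str = "multiplicative_random") -> list[MRResult]:
    """Weighted least squares of beta_y on the exposure matrix, no intercept.

    Weights are se_y^-2; SEs carry a multiplicative over-dispersion scale
    floored at 1 (``effects="fixed"`` disables it); p-values are normal.
    With k = 1 this is exactly the regression form of univariable IVW.
    """
    x = inp.beta_x
    y = inp.beta_y
    j, k = x.shape
    w = 1.0 / inp.se_y**2

    if np.linalg.matrix_rank(x) < k:
        raise RankDeficiencyError(
            f"exposure matrix has rank < {k}; collinear exposures"
        )
    xtw = x.T * w
    a = xtw @ x
    coef = np.linalg.solve(a, xtw @ y)
    resid = y - x @ coef
    dof = j - k
    rss_w = float((w * resid**2).sum())
    scale = 1.0
    if effects == "multiplicative_random" and dof > 0:
        scale = max(1.0, math.sqrt(rss_w / dof))
    cov = np.linalg.inv(a) * scale**2
    se = np.sqrt(np.diag(cov))

    results = []
    for i, name in enumerate(inp.exposure_names):
        est, s = float(coef[i]), float(se[i])
        pval = 2.0 * stats.norm.sf(abs(est) / s)
        results.append(
            MRResult(
                method="mvmr",
                estimate=est,
                se=s,
                ci_low=est - Z95 * s,
                ci_high=est + Z95 * s,
                pval=float(pval),
                n_snp=j,
                meta={
                    "exposure": name,
                    "k_exposures": k,
                    "overdispersion_scale": scale,
                },
            )
        )
    return results


@dataclass
class MediationResult:
    """Difference-method decomposition: total = direct + indirect exactly."""

    total_estimate: float
    total_se: float
    direct_estimate: float
    direct_se: float
    indirect_estimate: float
    indirect_se: float
    proportion_mediated: float
    pm_ci_low: float
    pm_ci_high: float
    mediator_names: list
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "total_estimate",
                "total_se",
                "direct_estimate",
                "direct_se",
                "indirect_estimate",
                "indirect_se",
                "proportion_mediated",
                "pm_ci_low",
                "pm_ci_high",
            )
        }
        out["mediator_names"] = list(self.mediator_names)
        out["meta"] = dict(self.meta)
        return out


def mediate(
    total: MRResult, direct: MRResult, mediator_names: list | None = None
) -> MediationResult:
    """Difference-method mediation: indirect = total - direct.

    ``se_indirect = sqrt(se_total^2 + se_direct^2)`` under the independence
    approximation; the proportion mediated PM = indirect/total gets a
    delta-method 95% CI for the ratio. PM outside [0, 1] is reported with a
    warning, never clipped. Binary-outcome inputs must both be on the
    log-odds scale (non-collapsibility caveat noted in metadata).
    """
    t, d = total.estimate, direct.estimate
    if t == 0:
        raise ZeroDivisionError("proportion mediated undefined: total effect is 0")
    st, sd = total.se, direct.se
    indirect = t - d
    se_ind = math.sqrt(st**2 + sd**2)
    pm = indirect / t
    # delta method on PM = 1 - D/T with independent (T, D):
    var_pm = (d / t**2) ** 2 * st**2 + sd**2 / t**2
    se_pm = math.sqrt(var_pm)
    if not 0.0 <= pm <= 1.0:
        warnings.warn(
            f"proportion mediated {pm:.3f} outside [0, 1]; reported unclipped",
            stacklevel=2,
        )
    return MediationResult(
        total_estimate=t,
        total_se=st,
        direct_estimate=d,
        direct_se=sd,
        indirect_estimate=indirect,
        indirect_se=se_ind,
        proportion_mediated=pm,
        pm_ci_low=pm - Z95 * se_pm,
        pm_ci_high=pm + Z95 * se_pm,
        mediator_names=list(mediator_names or []),
        meta={
            "pm_se": se_pm,
            "se_method": "delta, independent total/direct",
            "scale_note": "binary outcomes decomposed on the log-odds scale",
        },
    )
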