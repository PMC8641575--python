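"""Univariable MR estimators and heterogeneity/pleiotropy diagnostics.

Implements the Wald ratio with delta-method standard errors, fixed- and
multiplicative-random-effects IVW, Cochran's Q and the I^2 index, MR-Egger
regression with its intercept test, the weighted-median estimator with a
parametric bootstrap SE, the joint-normal maximum-likelihood estimator, and
leave-one-out IVW.

Conventions: estimates are per 1 SD of the exposure, on the log-odds scale
for binary outcomes (exponentiate via :meth:`MRResult.or_scale`). The
random-effects IVW uses multiplicative over-dispersion with the scale
floored at 1 (under-dispersion is never credited); MR-Egger p-values use a
t distribution with J-2 degrees of freedom, IVW a normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .harmonize import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge."""


@dataclass
class MRResult:
    """One estimator's causal estimate with its diagnostics."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q: float | None = None
    q_pval: float | None = None
    i2: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    meta: dict = field(default_factory=dict)

    def or_scale(self) -> dict:
        """Exponentiated estimate and CI, for binary (log-odds) outcomes."""
        return {
            "or": math.exp(self.estimate),
            "ci_low": math.exp(self.ci_low),
            "ci_high": math.exp(self.ci_high),
        }

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "method",
                "estimate",
                "se",
                "ci_low",
                "ci_high",
                "pval",
                "n_snp",
                "q",
                "q_pval",
                "i2",
                "egger_intercept",
                "intercept_se",
                "intercept_pval",
            )
        }
        out["meta"] = dict(self.meta)
        return out


@dataclass(frozen=True)
class QResult:
    q: float
    q_pval: float
    i2: float
    heterogeneous: bool  # I^2 > 25% and p_Q < 0.05


def wald_ratio(beta_x, se_x, beta_y, se_y, second_order: bool = False):
    """Per-SNP causal estimate beta_y/beta_x with delta-method SE.

    First order: se = se_y/|beta_x|. The second-order option adds the
    beta_y^2 * se_x^2 / beta_x^4 term.
    """
    if beta_x == 0:
        raise ZeroDivisionError("wald_ratio undefined for beta_x = 0")
    estimate = beta_y / beta_x
    if second_order:
        se = math.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        se = se_y / abs(beta_x)
    return estimate, se


def _ratios_weights(hset: HarmonizedSet):
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ZeroDivisionError("beta_x = 0 for some SNP; Wald ratio undefined")
    ratios = by / bx
    weights = (bx / sy) ** 2  # inverse first-order delta variance
    return ratios, weights


def ivw(hset: HarmonizedSet, effects: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``effects``: ``"fixed"`` or ``"multiplicative_random"`` (the default;
    the fixed-effect SE is inflated by max(1, sqrt(Q/(J-1)))). With a single
    SNP the result reduces exactly to the Wald ratio.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects flavor {effects!r}")
    j = len(hset)
    if j < 1:
        raise ValueError("ivw requires at least one SNP")
    ratios, w = _ratios_weights(hset)
    sw = w.sum()
    estimate = float((w * ratios).sum() / sw)
    se_fixed = sw**-0.5

    q = q_pval = i2 = None
    scale = 1.0
    if j >= 2:
        qr = _cochran(ratios, w, estimate, j)
        q, q_pval, i2 = qr.q, qr.q_pval, qr.i2
        if effects == "multiplicative_random":
            scale = max(1.0, math.sqrt(q / (j - 1)))
    se = float(se_fixed * scale)
    pval = 2.0 * stats.norm.sf(abs(estimate) / se)
    return MRResult(
        method=f"ivw_{effects}",
        estimate=estimate,
        se=se,
        ci_low=estimate - Z95 * se,
        ci_high=estimate + Z95 * se,
        pval=float(pval),
        n_snp=j,
        q=q,
        q_pval=q_pval,
        i2=i2,
        meta={"se_fixed": float(se_fixed), "overdispersion_scale": scale},
    )


def _cochran(ratios, w, estimate, j) -> QResult:
    q = float((w * (ratios - estimate) ** 2).sum())
    q_pval = float(stats.chi2.sf(q, j - 1))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (j - 1)) / q) * 100.0
    return QResult(q=q, q_pval=q_pval, i2=i2, heterogeneous=(i2 > 25.0 and q_pval < 0.05))


def cochran_q(hset: HarmonizedSet) -> QResult:
    """Cochran's Q across Wald ratios, its chi-square p, and I^2 (percent).

    Heterogeneity is flagged when I^2 > 25% and p_Q < 0.05.
    """
    j = len(hset)
    if j < 2:
        raise ValueError("cochran_q requires at least two SNPs")
    ratios, w = _ratios_weights(hset)
    estimate = float((w * ratios).sum() / w.sum())
    return _cochran(ratios, w, estimate, j)


def mr_egger(hset: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with an intercept.

    SNPs are first oriented so every beta_x is non-negative. Weights are
    se_y^-2; both SEs carry a multiplicative over-dispersion scale floored
    at 1; p-values are two-sided t with J-2 df. The intercept estimates
    average directional pleiotropy (p < 0.05 flags pleiotropy).
    """
    j = len(hset)
    if j < 3:
        raise ValueError("mr_egger requires at least three SNPs")
    bx, sx, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise ValueError("mr_egger requires variation in beta_x")

    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    a = xtw @ x
    coef = np.linalg.solve(a, xtw @ by)
    resid = by - x @ coef
    dof = j - 2
    rss_w = float((w * resid**2).sum())
    scale = max(1.0, math.sqrt(rss_w / dof))
    cov = np.linalg.inv(a) * scale**2
    se = np.sqrt(np.diag(cov))

    tq = stats.t.ppf(0.975, dof)
    slope, slope_se = float(coef[1]), float(se[1])
    intercept, intercept_se = float(coef[0]), float(se[0])
    p_slope = 2.0 * stats.t.sf(abs(slope) / slope_se, dof)
    p_int = 2.0 * stats.t.sf(abs(intercept) / intercept_se, dof)
    return MRResult(
        method="mr_egger",
        estimate=slope,
        se=slope_se,
        ci_low=slope - tq * slope_se,
        ci_high=slope + tq * slope_se,
        pval=float(p_slope),
        n_snp=j,
        egger_intercept=intercept,
        intercept_se=intercept_se,
        intercept_pval=float(p_int),
        meta={"overdispersion_scale": scale, "pvalue_dist": f"t({dof})"},
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = np.cumsum(w)
    p = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 5000, seed: int | None = None
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    The point estimate interpolates the ordered Wald ratios at cumulative
    standardized weight 1/2 with p_j = (S_j - w_j/2)/S_J. The SE is the SD
    of estimates recomputed on ``n_boot`` parametric resamples of
    (beta_x, beta_y); with ``n_boot = 0`` only the point estimate is
    returned (SE/p are NaN).
    """
    j = len(hset)
    if j < 3:
        raise ValueError("weighted_median requires at least three SNPs")
    bx, sx, by, sy = hset.arrays()
    ratios, w = _ratios_weights(hset)
    estimate = _weighted_median(ratios, w)

    if n_boot <= 0:
        return MRResult(
            method="weighted_median",
            estimate=estimate,
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            pval=float("nan"),
            n_snp=j,
            meta={"n_boot": 0},
        )

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    bx_b[bx_b == 0] = np.finfo(float).tiny
    r_b = by_b / bx_b
    w_b = (bx_b / sy) ** 2
    order = np.argsort(r_b, axis=1)
    r_s = np.take_along_axis(r_b, order, axis=1)
    w_s = np.take_along_axis(w_b, order, axis=1)
    s = np.cumsum(w_s, axis=1)
    p = (s - w_s / 2.0) / s[:, -1:]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, p[i], r_s[i])
    se = float(boots.std(ddof=1))
    pval = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else float("nan")
    return MRResult(
        method="weighted_median",
        estimate=estimate,
        se=se,
        ci_low=estimate - Z95 * se,
        ci_high=estimate + Z95 * se,
        pval=float(pval),
        n_snp=j,
        meta={"n_boot": n_boot, "seed": seed},
    )


def max_likelihood(hset: HarmonizedSet) -> MRResult:
    """Joint-normal maximum-likelihood estimate of the causal effect.

    Maximizes the likelihood of beta_x_j ~ N(gamma_j, se_x_j^2),
    beta_y_j ~ N(theta*gamma_j, se_y_j^2) over (theta, gamma), profiling
    the gamma_j in closed form; the SE comes from the curvature of the
    profile log-likelihood at the maximum. Initialized at the IVW estimate.
    """
    j = len(hset)
    if j < 1:
        raise ValueError("max_likelihood requires at least one SNP")
    bx, sx, by, sy = hset.arrays()
    vx, vy = sx**2, sy**2

    def nll(theta: float) -> float:
        gam = (bx / vx + theta * by / vy) / (1.0 / vx + theta**2 / vy)
        return 0.5 * float(
            (((bx - gam) ** 2) / vx + ((by - theta * gam) ** 2) / vy).sum()
        )

    theta0 = ivw(hset, effects="fixed").estimate if j >= 1 else 0.0
    res = optimize.minimize(
        lambda t: nll(t[0]), x0=[theta0], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if not res.success:
        raise ConvergenceError(f"max_likelihood failed: {res.message}")
    theta = float(res.x[0])

    h = 1e-4 * max(1.0, abs(theta))
    d2 = (nll(theta + h) - 2.0 * nll(theta) + nll(theta - h)) / h**2
    if d2 <= 0:
        raise ConvergenceError("non-positive curvature at the ML optimum")
    se = 1.0 / math.sqrt(d2)
    pval = 2.0 * stats.norm.sf(abs(theta) / se)
    return MRResult(
        method="max_likelihood",
        estimate=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=float(pval),
        n_snp=j,
        meta={"nll": float(res.fun), "iterations": int(res.nit)},
    )


def leave_one_out(
    hset: HarmonizedSet, effects: str = "multiplicative_random", alpha: float = 0.05
) -> pd.DataFrame:
    """IVW recomputed J times, each excluding one SNP.

    Flags SNPs whose removal flips the estimate's sign or moves the causal
    test across ``alpha``.
    """
    j = len(hset)
    if j < 3:
        raise ValueError("leave_one_out requires at least three SNPs")
    full = ivw(hset, effects=effects)
    rows = []
    snps = hset.data["snp"].tolist()
    for snp in snps:
        res = ivw(hset.drop([snp]), effects=effects)
        rows.append(
            {
                "snp": snp,
                "estimate": res.estimate,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
                "delta_estimate": res.estimate - full.estimate,
                "sign_change": np.sign(res.estimate) != np.sign(full.estimate),
                "significance_change": (res.pval < alpha) != (full.pval < alpha),
            }
        )
    return pd.DataFrame(rows)
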