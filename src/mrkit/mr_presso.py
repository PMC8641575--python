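"""Residual-sum-of-squares pleiotropy test with outlier detection
(global test, per-SNP outlier test, distortion test, corrected IVW).

The observed statistic is RSS = sum_j w_j (beta_y_j - theta_(-j) beta_x_j)^2
with w_j = se_y_j^-2 and theta_(-j) the weighted regression-through-origin
slope excluding SNP j. Its null distribution is built by parametric
simulation; empirical p-values use (1 + #{sim >= obs}) / (1 + n_sim), so the
minimum attainable p is 1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import MRResult, ivw
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_ids: list
    outlier_pvals: dict  # snp -> Bonferroni-adjusted empirical p
    distortion_pval: float | None
    raw_estimate: MRResult
    corrected_estimate: MRResult
    n_sim: int
    seed: int | None
    meta: dict = field(default_factory=dict)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (weighted through-origin regression)."""
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    effects: str = "multiplicative_random",
    distortion: bool = True,
) -> PressoResult:
    """Global pleiotropy test, outlier detection, and corrected estimate.

    Per-SNP outliers are called at Bonferroni-adjusted empirical p <
    ``outlier_alpha`` and removed before re-running IVW; the distortion test
    (advisory) compares the raw-vs-corrected shift against slopes from
    random outlier-sized removals. Seed-deterministic.
    """
    j = len(hset)
    if j < 4:
        raise ValueError("presso requires at least four SNPs")
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy**2
    snps = hset.data["snp"].tolist()
    rng = np.random.default_rng(seed)

    theta_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    # simulated null: beta'_x ~ N(beta_x, se_x), beta'_y ~ N(theta_(-j) beta_x, se_y)
    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_s = _loo_slopes(bx_s, by_s, w)
    res_s = w * (by_s - theta_s * bx_s) ** 2
    rss_s = res_s.sum(axis=1)

    global_pval = float((1 + (rss_s >= rss_obs).sum()) / (1 + n_sim))

    p_snp = (1 + (res_s >= res_obs).sum(axis=0)) / (1 + n_sim)
    p_adj = np.minimum(p_snp * j, 1.0)
    outlier_mask = p_adj < outlier_alpha
    outlier_ids = [s for s, o in zip(snps, outlier_mask) if o]
    if outlier_mask.all():
        raise ValueError("all SNPs flagged as outliers; no corrected set remains")

    raw = ivw(hset, effects=effects)
    corrected = ivw(hset.drop(outlier_ids), effects=effects)

    distortion_pval = None
    if distortion and outlier_ids:
        n_out = len(outlier_ids)
        obs_shift = abs(raw.estimate - corrected.estimate) / max(
            abs(corrected.estimate), np.finfo(float).tiny
        )
        shifts = np.empty(n_sim)
        sxx_full = float((w * bx * bx).sum())
        sxy_full = float((w * bx * by).sum())
        for i in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            sxx = sxx_full - float((w[drop] * bx[drop] * bx[drop]).sum())
            sxy = sxy_full - float((w[drop] * bx[drop] * by[drop]).sum())
            theta_i = sxy / sxx
            shifts[i] = abs(raw.estimate - theta_i) / max(
                abs(theta_i), np.finfo(float).tiny
            )
        distortion_pval = float((1 + (shifts >= obs_shift).sum()) / (1 + n_sim))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_ids=outlier_ids,
        outlier_pvals={s: float(p) for s, p in zip(snps, p_adj)},
        distortion_pval=distortion_pval,
        raw_estimate=raw,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
        meta={"outlier_alpha": outlier_alpha, "effects": effects},
    )
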