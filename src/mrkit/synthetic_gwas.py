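"""Synthetic two-sample GWAS summary statistics with known causal structure.

Generates exposure/outcome summary-statistic tables from a configured truth
(per-SNP instrument effects, a causal effect, optional horizontal pleiotropy)
plus allele-encoding corruption (swaps, strand flips, palindromic rewrites)
so that every downstream stage can be verified against ground truth.

Effects are on standardized scales: the exposure in SD units, binary
outcomes on the log-odds scale. Instruments are generated mutually
independent (no LD); simulated SNPs are spaced far apart so clumping with a
sparse LD table leaves them untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import SUMSTAT_COLUMNS, validate_sumstats

# non-palindromic (effect, other) pairs only; palindromes are introduced
# explicitly by corrupt_alleles so fixtures stay controllable
_ALLELE_PAIRS = [
    ("A", "G"),
    ("G", "A"),
    ("A", "C"),
    ("C", "A"),
    ("T", "G"),
    ("G", "T"),
    ("T", "C"),
    ("C", "T"),
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_PVAL_FLOOR = 1e-300


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a two-sample summary-statistic simulation.

    ``theta`` is the true causal effect (outcome units per 1 SD exposure,
    log-odds when ``binary_outcome``). ``gamma_mean``/``gamma_sd`` govern the
    SNP-exposure effects; ``pleiotropy_mean``/``pleiotropy_sd`` the direct
    SNP-outcome effects of the ``invalid_fraction`` of invalid instruments.
    """

    n_snps: int
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    theta: float = 0.0
    gamma_mean: float = 0.08
    gamma_sd: float = 0.02
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    binary_outcome: bool = False
    case_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be >= 2")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.binary_outcome and not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1) for binary outcomes")
        for name in ("theta", "gamma_mean", "gamma_sd", "pleiotropy_mean", "pleiotropy_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("effect-size SDs must be non-negative")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_ids: list
    corruption_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "action"])
    )

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta,
                "gamma": self.gamma.tolist(),
                "alpha": self.alpha.tolist(),
                "invalid_ids": list(self.invalid_ids),
                "corruption_log": self.corruption_log.to_dict(orient="records"),
            },
            sort_keys=True,
        )


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    return np.maximum(2.0 * stats.norm.sf(z), _PVAL_FLOOR)


def simulate_two_sample(config: SimulationConfig):
    """Draw one exposure table, one outcome table, and the generating truth.

    Per SNP j: MAF_j ~ U(maf_range); se_Xj = 1/sqrt(2 MAF_j (1-MAF_j) n_exposure);
    observed beta_Xj ~ N(gamma_j, se_Xj); true outcome effect
    Gamma_j = theta*gamma_j + alpha_j; se_Yj analogous with n_outcome (binary
    outcomes get the 1/(K(1-K)) log-odds variance inflation);
    beta_Yj ~ N(Gamma_j, se_Yj) with noise independent of the exposure draw
    (non-overlapping samples). Identical seeds give byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)

    n_invalid = int(round(config.invalid_fraction * j))
    invalid_idx = rng.choice(j, size=n_invalid, replace=False)
    alpha = np.zeros(j)
    alpha[invalid_idx] = rng.normal(
        config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid
    )

    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * config.n_exposure)
    var_y = het * config.n_outcome
    if config.binary_outcome:
        var_y = var_y * config.case_fraction * (1.0 - config.case_fraction)
    se_y = 1.0 / np.sqrt(var_y)

    beta_x = gamma + rng.standard_normal(j) * se_x
    big_gamma = config.theta * gamma + alpha
    beta_y = big_gamma + rng.standard_normal(j) * se_y

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    effect = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    # effect allele is the minor or major allele with equal probability
    eaf = np.where(rng.random(j) < 0.5, maf, 1.0 - maf)

    snp = np.array([f"rs{k + 1}" for k in range(j)])
    chrom = (np.arange(j) % 22) + 1
    # same-chromosome SNPs sit >10,000 kb apart so they never co-clump
    pos = 1_000_000 + (np.arange(j) // 22) * 50_000_000

    def _table(beta, se, n):
        return pd.DataFrame(
            {
                "snp": snp,
                "chr": chrom,
                "pos": pos,
                "effect_allele": effect,
                "other_allele": other,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": _two_sided_p(beta, se),
                "n": n,
            },
            columns=SUMSTAT_COLUMNS,
        )

    exposure = _table(beta_x, se_x, config.n_exposure)
    outcome = _table(beta_y, se_y, config.n_outcome)
    truth = SimTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        invalid_ids=sorted(snp[invalid_idx].tolist()),
    )
    return exposure, outcome, truth


@dataclass(frozen=True)
class MediationSimConfig:
    """Generating parameters for an exposure -> mediator -> outcome design.

    ``theta_direct`` is the exposure effect on the outcome not through the
    mediator, ``beta_xm`` the exposure effect on the mediator and
    ``theta_my`` the mediator effect on the outcome, so the true total
    effect is ``theta_direct + beta_xm * theta_my``. The first
    ``n_snps_exposure`` SNPs instrument the exposure only, the remaining
    ``n_snps_mediator`` the mediator only. Each GWAS (exposure, mediator,
    outcome, and an independent outcome replicate for total-effect
    estimation) gets independent sampling noise.
    """

    n_snps_exposure: int
    n_snps_mediator: int
    n_gwas: int = 200_000
    theta_direct: float = 0.2
    beta_xm: float = 0.5
    theta_my: float = 0.2
    gamma_mean: float = 0.08
    gamma_sd: float = 0.01
    maf: float = 0.25
    seed: int | None = None

    @property
    def true_total(self) -> float:
        return self.theta_direct + self.beta_xm * self.theta_my

    @property
    def true_proportion_mediated(self) -> float:
        return self.beta_xm * self.theta_my / self.true_total


@dataclass
class MediationSimData:
    """Per-SNP summary statistics for the mediation design (arrays aligned
    on the instrument union; ``is_exposure_snp`` marks the exposure block)."""

    snps: list
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_m: np.ndarray
    se_m: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    beta_y_indep: np.ndarray  # independent outcome replicate
    is_exposure_snp: np.ndarray
    config: MediationSimConfig


def simulate_mediation(config: MediationSimConfig) -> MediationSimData:
    """Simulate summary statistics under a one-mediator causal chain."""
    rng = np.random.default_rng(config.seed)
    jx, jm = config.n_snps_exposure, config.n_snps_mediator
    j = jx + jm
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=jx)  # SNP -> X
    phi = rng.normal(config.gamma_mean, config.gamma_sd, size=jm)  # SNP -> M

    true_x = np.concatenate([gamma, np.zeros(jm)])
    true_m = np.concatenate([config.beta_xm * gamma, phi])
    true_y = config.theta_direct * true_x + config.theta_my * true_m

    se = np.full(j, 1.0 / math.sqrt(2 * config.maf * (1 - config.maf) * config.n_gwas))
    return MediationSimData(
        snps=[f"rs{k + 1}" for k in range(j)],
        beta_x=true_x + rng.standard_normal(j) * se,
        se_x=se.copy(),
        beta_m=true_m + rng.standard_normal(j) * se,
        se_m=se.copy(),
        beta_y=true_y + rng.standard_normal(j) * se,
        se_y=se.copy(),
        beta_y_indep=true_y + rng.standard_normal(j) * se,
        is_exposure_snp=np.arange(j) < jx,
        config=config,
    )


def corrupt_alleles(
    table: pd.DataFrame,
    swap_fraction: float = 0.0,
    strand_fraction: float = 0.0,
    palindromic_fraction: float = 0.0,
    seed: int | None = None,
    palindromic_eaf: float | None = None,
):
    """Apply allele-encoding corruption to disjoint random SNP subsets.

    * swap: effect/other alleles exchanged, beta negated, EAF reflected;
    * strand: both alleles complemented (A<->T, C<->G), beta/EAF untouched;
    * palindromic: alleles rewritten as an A/T or C/G pair, EAF optionally
      forced to ``palindromic_eaf``.

    Returns the corrupted copy and a log DataFrame (snp, action) so that
    harmonization can be scored against what was applied.
    """
    for name, frac in (
        ("swap_fraction", swap_fraction),
        ("strand_fraction", strand_fraction),
        ("palindromic_fraction", palindromic_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    validate_sumstats(table, "corrupt_alleles input")

    j = len(table)
    n_swap = int(round(swap_fraction * j))
    n_strand = int(round(strand_fraction * j))
    n_pal = int(round(palindromic_fraction * j))
    if n_swap + n_strand + n_pal > j:
        raise ValueError("corruption fractions overlap: union exceeds table size")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(j)
    swap_idx = perm[:n_swap]
    strand_idx = perm[n_swap : n_swap + n_strand]
    pal_idx = perm[n_swap + n_strand : n_swap + n_strand + n_pal]

    out = table.copy().reset_index(drop=True)
    log_rows = []

    for i in swap_idx:
        e, o = out.at[i, "effect_allele"], out.at[i, "other_allele"]
        out.at[i, "effect_allele"], out.at[i, "other_allele"] = o, e
        out.at[i, "beta"] = -out.at[i, "beta"]
        out.at[i, "eaf"] = 1.0 - out.at[i, "eaf"]
        log_rows.append((out.at[i, "snp"], "swap"))

    for i in strand_idx:
        out.at[i, "effect_allele"] = _COMPLEMENT[out.at[i, "effect_allele"]]
        out.at[i, "other_allele"] = _COMPLEMENT[out.at[i, "other_allele"]]
        log_rows.append((out.at[i, "snp"], "strand"))

    for i in pal_idx:
        e = "A" if rng.random() < 0.5 else "C"
        out.at[i, "effect_allele"] = e
        out.at[i, "other_allele"] = _COMPLEMENT[e]
        if palindromic_eaf is not None:
            out.at[i, "eaf"] = palindromic_eaf
        log_rows.append((out.at[i, "snp"], "palindromic"))

    log = pd.DataFrame(log_rows, columns=["snp", "action"])
    return out, log
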