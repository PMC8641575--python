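"""Align exposure and outcome summary statistics onto the same effect allele.

Resolves effect/other allele swaps and strand flips from the allele codes,
and palindromic (A/T, C/G) ambiguity from effect-allele frequencies: a
palindromic SNP is inferable only when its minor allele frequency is
strictly below the threshold (default 0.42) in both datasets and the
frequency-implied orientations agree; otherwise it is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import validate_sumstats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = ["snp", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"]

ACTIONS = (
    "kept",
    "sign-flipped",
    "strand-flipped",
    "dropped-palindromic",
    "dropped-missing",
    "dropped-mismatch",
)


def is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT[a] == b


@dataclass
class HarmonizedSet:
    """Aligned per-SNP effect vectors ready for estimation.

    ``data`` has columns snp, beta_x, se_x, beta_y, se_y, eaf_x, eaf_y;
    ``audit`` records one (snp, action) per exposure SNP.
    """

    data: pd.DataFrame
    audit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "action"])
    )

    def __post_init__(self):
        d = self.data
        if d["snp"].duplicated().any():
            raise ValueError("duplicate snp in harmonized data")
        if len(d) and not ((d["se_x"] > 0).all() and (d["se_y"] > 0).all()):
            raise ValueError("harmonized standard errors must be positive")

    def __len__(self) -> int:
        return len(self.data)

    def arrays(self):
        d = self.data
        return (
            d["beta_x"].to_numpy(float),
            d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float),
            d["se_y"].to_numpy(float),
        )

    def subset(self, snps) -> "HarmonizedSet":
        keep = self.data["snp"].isin(list(snps))
        return HarmonizedSet(
            data=self.data.loc[keep].reset_index(drop=True),
            audit=self.audit,
        )

    def drop(self, snps) -> "HarmonizedSet":
        return self.subset(set(self.data["snp"]) - set(snps))

    @classmethod
    def from_aligned(cls, exposure: pd.DataFrame, outcome: pd.DataFrame) -> "HarmonizedSet":
        """Fast merge of two tables already known to share effect alleles.

        Intended for simulated data where both tables were generated on the
        same allele coding; no allele checks are performed.
        """
        merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
        data = merged[
            ["snp", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"]
        ].copy()
        audit = pd.DataFrame({"snp": data["snp"], "action": "kept"})
        return cls(data=data, audit=audit)


def _resolve(e1, o1, e2, o2, beta_y, eaf_y, eaf_x, maf_threshold):
    """Return (action, beta_y, eaf_y) for one SNP, aligned to (e1, o1)."""
    if is_palindromic(e1, o1):
        if {e2, o2} != {e1, o1}:
            return "dropped-mismatch", beta_y, eaf_y
        action = "kept"
        if e2 != e1:  # nominal label swap before frequency check
            beta_y, eaf_y, action = -beta_y, 1.0 - eaf_y, "sign-flipped"
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return "dropped-palindromic", beta_y, eaf_y
        if min(eaf_x, 1.0 - eaf_x) >= maf_threshold:
            return "dropped-palindromic", beta_y, eaf_y
        if min(eaf_y, 1.0 - eaf_y) >= maf_threshold:
            return "dropped-palindromic", beta_y, eaf_y
        if (eaf_x < 0.5) != (eaf_y < 0.5):
            return "dropped-palindromic", beta_y, eaf_y
        return action, beta_y, eaf_y

    if (e2, o2) == (e1, o1):
        return "kept", beta_y, eaf_y
    if (e2, o2) == (o1, e1):
        return "sign-flipped", -beta_y, 1.0 - eaf_y
    ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
    if (ce2, co2) == (e1, o1):
        return "strand-flipped", beta_y, eaf_y
    if (ce2, co2) == (o1, e1):
        return "sign-flipped", -beta_y, 1.0 - eaf_y
    return "dropped-mismatch", beta_y, eaf_y


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Matching is by snp identifier. Exposure SNPs absent from the outcome
    are audited ``dropped-missing`` (candidates for upstream proxy
    substitution). Palindromic SNPs with MAF at or above ``maf_threshold``
    in either dataset, or with discordant frequency-implied orientations,
    are audited ``dropped-palindromic``. Irreconcilable allele codes are
    ``dropped-mismatch``.
    """
    validate_sumstats(exposure, "exposure")
    validate_sumstats(outcome, "outcome")
    if not 0.0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must lie in (0, 0.5]")

    out_by_snp = outcome.set_index("snp")
    rows = []
    audit_rows = []
    for rec in exposure.itertuples(index=False):
        if rec.snp not in out_by_snp.index:
            audit_rows.append((rec.snp, "dropped-missing"))
            continue
        o = out_by_snp.loc[rec.snp]
        action, beta_y, eaf_y = _resolve(
            rec.effect_allele,
            rec.other_allele,
            o["effect_allele"],
            o["other_allele"],
            float(o["beta"]),
            float(o["eaf"]),
            float(rec.eaf),
            maf_threshold,
        )
        audit_rows.append((rec.snp, action))
        if action.startswith("dropped"):
            continue
        rows.append(
            (rec.snp, rec.beta, rec.se, beta_y, float(o["se"]), rec.eaf, eaf_y)
        )

    data = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    audit = pd.DataFrame(audit_rows, columns=["snp", "action"])
    return HarmonizedSet(data=data, audit=audit)
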