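"""Instrument selection: significance filtering, LD clumping, proxy search,
and instrument-strength (F statistic) calculation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import ld_lookup, validate_sumstats

GWAS_P_THRESHOLD = 5e-8


@dataclass
class InstrumentSet:
    """Selected instruments plus an audit of every exclusion.

    Every SNP of the original input appears exactly once in
    ``table['snp']`` union ``audit['snp']``.
    """

    table: pd.DataFrame
    audit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snps(self) -> list:
        return self.table["snp"].tolist()


def filter_significant(
    table: pd.DataFrame, p_threshold: float = GWAS_P_THRESHOLD
) -> InstrumentSet:
    """Keep rows with pval strictly below ``p_threshold``.

    The comparison is strict: a SNP with p exactly at the threshold is
    excluded and audited as ``p-threshold``.
    """
    validate_sumstats(table, "filter_significant input")
    keep = table["pval"] < p_threshold
    audit = pd.DataFrame(
        {"snp": table.loc[~keep, "snp"].to_numpy(), "reason": "p-threshold"}
    )
    return InstrumentSet(table=table.loc[keep].reset_index(drop=True), audit=audit)


def ld_clump(
    instruments: InstrumentSet | pd.DataFrame,
    ld: pd.DataFrame | Mapping | None,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
    strict: bool = False,
) -> InstrumentSet:
    """Greedy LD clumping: keep the smallest-p SNP, drop its LD partners.

    SNPs are visited in ascending p (ties broken by chromosome then
    position); each accepted SNP removes every not-yet-accepted SNP on the
    same chromosome within ``window_kb`` kilobases whose pairwise r2 is at
    least ``r2_threshold``. SNPs farther apart than the window are never
    clumped together. Pairs absent from the LD table count as r2 = 0 unless
    ``strict``, in which case they raise.
    """
    if isinstance(instruments, InstrumentSet):
        table, prior_audit = instruments.table, instruments.audit
    else:
        table, prior_audit = instruments, pd.DataFrame(columns=["snp", "reason"])
    if table[["chr", "pos"]].isna().any().any():
        raise ValueError("ld_clump requires chr and pos for every SNP")

    if ld is None:
        pairs: Mapping = {}
    elif isinstance(ld, pd.DataFrame):
        pairs = ld_lookup(ld)
    else:
        pairs = ld

    window_bp = window_kb * 1000.0
    order = table.sort_values(
        ["pval", "chr", "pos"], kind="mergesort"
    ).index.tolist()
    removed: dict = {}
    accepted: list = []
    for i in order:
        snp_i = table.at[i, "snp"]
        if snp_i in removed:
            continue
        accepted.append(i)
        chr_i, pos_i = table.at[i, "chr"], table.at[i, "pos"]
        for k in order:
            snp_k = table.at[k, "snp"]
            if k == i or k in accepted or snp_k in removed:
                continue
            if table.at[k, "chr"] != chr_i:
                continue
            if abs(table.at[k, "pos"] - pos_i) > window_bp:
                continue
            r2 = pairs.get((snp_i, snp_k))
            if r2 is None:
                if strict:
                    raise KeyError(f"no LD entry for pair ({snp_i}, {snp_k})")
                r2 = 0.0
            if r2 >= r2_threshold:
                removed[snp_k] = snp_i

    keep_mask = table.index.isin(accepted)
    new_audit = pd.DataFrame(
        {
            "snp": list(removed),
            "reason": [f"clumped-by:{v}" for v in removed.values()],
        }
    )
    audit = pd.concat([prior_audit, new_audit], ignore_index=True)
    return InstrumentSet(table=table.loc[keep_mask].reset_index(drop=True), audit=audit)


def substitute_proxies(
    missing: Iterable[str], proxy_table: pd.DataFrame, r2_min: float = 0.8
) -> dict:
    """Map each missing SNP to its best proxy with r2 strictly above r2_min.

    Candidates are rows of ``proxy_table`` linking the missing SNP to
    another identifier; the highest-r2 candidate wins, ties broken by
    lexicographic identifier order. SNPs with no qualifying candidate are
    absent from the returned mapping.
    """
    mapping: dict = {}
    if len(proxy_table) == 0:
        return mapping
    for snp in missing:
        cand_a = proxy_table.loc[proxy_table["snp_a"] == snp, ["snp_b", "r2"]]
        cand_b = proxy_table.loc[proxy_table["snp_b"] == snp, ["snp_a", "r2"]]
        cands = [
            *zip(cand_a["snp_b"], cand_a["r2"]),
            *zip(cand_b["snp_a"], cand_b["r2"]),
        ]
        cands = [(p, r2) for p, r2 in cands if r2 > r2_min]
        if cands:
            # best r2 first, then identifier order for determinism
            cands.sort(key=lambda t: (-t[1], t[0]))
            mapping[snp] = cands[0][0]
    return mapping


@dataclass(frozen=True)
class InstrumentStrength:
    f: float
    weak: bool  # F <= 10


def instrument_strength(r2_total: float, n: int, k: int) -> InstrumentStrength:
    """Multi-instrument F statistic: F = (r2/(1-r2)) * ((n-k-1)/k).

    ``r2_total`` is the proportion of exposure variance jointly explained by
    the k instruments in a GWAS of n subjects. F <= 10 flags a weak set.
    """
    if not 0.0 < r2_total < 1.0:
        raise ValueError("r2_total must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    f = (r2_total / (1.0 - r2_total)) * ((n - k - 1) / k)
    return InstrumentStrength(f=f, weak=f <= 10.0)


def variance_explained(table: pd.DataFrame) -> float:
    """Total r2 of a set of instruments on a standardized trait.

    Per-SNP contribution 2*EAF*(1-EAF)*beta^2, summed (instruments assumed
    independent post-clumping).
    """
    eaf = np.asarray(table["eaf"], dtype=float)
    beta = np.asarray(table["beta"], dtype=float)
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))
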