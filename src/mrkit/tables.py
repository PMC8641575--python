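"""Reading, writing and validation of GWAS summary-statistic and LD tables.

A summary-statistic table is a pandas DataFrame with one row per SNP and
columns ``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
An LD table has columns ``snp_a, snp_b, r2`` (symmetric by convention).
Both are exchanged on disk as tab-separated text with a header line.
"""

from __future__ import annotations

import pandas as pd

SUMSTAT_COLUMNS = [
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

LD_COLUMNS = ["snp_a", "snp_b", "r2"]

VALID_ALLELES = frozenset("ACGT")


class TableError(ValueError):
    """Raised when a summary-statistic or LD table violates its contract."""


def validate_sumstats(table: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    """Validate a summary-statistic table, returning it unchanged.

    Checks column presence, unique SNP identifiers, positive standard
    errors, allele frequencies in (0, 1), p-values in (0, 1], and
    single-base A/C/G/T alleles with effect != other.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"{name}: missing columns {missing}")
    if table["snp"].duplicated().any():
        dupes = table.loc[table["snp"].duplicated(), "snp"].tolist()
        raise TableError(f"{name}: duplicate snp identifiers {dupes[:5]}")
    if not (table["se"] > 0).all():
        raise TableError(f"{name}: non-positive standard errors")
    eaf = table["eaf"]
    if not ((eaf > 0) & (eaf < 1)).all():
        raise TableError(f"{name}: eaf outside (0, 1)")
    pv = table["pval"]
    if not ((pv > 0) & (pv <= 1)).all():
        raise TableError(f"{name}: pval outside (0, 1]")
    for col in ("effect_allele", "other_allele"):
        bad = ~table[col].isin(list(VALID_ALLELES))
        if bad.any():
            raise TableError(
                f"{name}: non-ACGT alleles {table.loc[bad, col].unique().tolist()}"
            )
    same = table["effect_allele"] == table["other_allele"]
    if same.any():
        raise TableError(f"{name}: effect and other allele identical")
    return table


def read_sumstats(path, validate: bool = True) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"snp": str, "effect_allele": str, "other_allele": str},
    )
    if validate:
        validate_sumstats(table, name=str(path))
    return table


def write_sumstats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=SUMSTAT_COLUMNS)


def read_ld(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    missing = [c for c in LD_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")
    r2 = table["r2"]
    if not ((r2 >= 0) & (r2 <= 1)).all():
        raise TableError(f"{path}: r2 outside [0, 1]")
    return table


def write_ld(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=LD_COLUMNS)


def ld_lookup(ld: pd.DataFrame) -> dict:
    """Build a symmetric {(a, b): r2} lookup; duplicate pairs keep the max."""
    out: dict = {}
    for a, b, r2 in zip(ld["snp_a"], ld["snp_b"], ld["r2"]):
        for key in ((a, b), (b, a)):
            if key not in out or r2 > out[key]:
                out[key] = float(r2)
    return out
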