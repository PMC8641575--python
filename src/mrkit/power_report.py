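"""Analytical power, Bonferroni classification, and the end-to-end pipeline.

Power follows the standard two-sided normal approximation for the IVW
estimator. Continuous outcomes use non-centrality sqrt(n * r2) * beta_alt.
Binary outcomes first map the alternative odds ratio to an effect on the
observed scale, b = K*(OR/(1 + K*(OR - 1)) - 1), with sampling variance
(K*(1 - K) - b^2)/(n * r2), and apply the same formula; K is the proportion
of cases. At the null the two-sided power equals alpha exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import estimators, instruments as instr, mr_presso, mvmr_mediation as mm
from .harmonize import harmonize as _harmonize
from .tables import read_ld, read_sumstats


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the analytical power calculation.

    Exactly one of ``beta_alt`` (continuous, SD units) or ``or_alt``
    (binary, odds ratio; requires ``k_cases``) must be given.
    """

    n: int
    r2: float
    alpha: float = 0.05
    beta_alt: float | None = None
    or_alt: float | None = None
    k_cases: float | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if (self.beta_alt is None) == (self.or_alt is None):
            raise ValueError("give exactly one of beta_alt or or_alt")
        if self.or_alt is not None:
            if self.or_alt <= 0:
                raise ValueError("or_alt must be positive")
            if self.k_cases is None or not 0.0 < self.k_cases < 1.0:
                raise ValueError("binary outcomes require k_cases in (0, 1)")


def mr_power(params: PowerParams) -> float:
    """Two-sided power of the IVW causal test under the given alternative."""
    z = stats.norm.ppf(1.0 - params.alpha / 2.0)
    if params.beta_alt is not None:
        ncp = math.sqrt(params.n * params.r2) * abs(params.beta_alt)
    else:
        k, or_alt = params.k_cases, params.or_alt
        b = k * (or_alt / (1.0 + k * (or_alt - 1.0)) - 1.0)
        v = (k * (1.0 - k) - b**2) / (params.n * params.r2)
        if v <= 0:
            raise ValueError("degenerate variance; check or_alt and k_cases")
        ncp = abs(b) / math.sqrt(v)
    return float(stats.norm.cdf(-z + ncp) + stats.norm.cdf(-z - ncp))


def bonferroni_classify(
    pvals: pd.DataFrame,
    n_exposures: int = 3,
    n_outcomes: int = 13,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each (exposure, outcome, p) row.

    The exact threshold alpha/(n_exposures * n_outcomes) separates
    ``significant`` from ``suggestive`` (p below ``alpha``); everything
    else is ``null``. The classes partition the rows.
    """
    threshold = alpha / (n_exposures * n_outcomes)
    p = pvals["p"].to_numpy(float)
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    cls = np.where(p < threshold, "significant", np.where(p < alpha, "suggestive", "null"))
    out = pvals.copy()
    out["class"] = cls
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class PipelineReport:
    primary: pd.DataFrame
    mvmr: pd.DataFrame
    mediation: pd.DataFrame
    forest: pd.DataFrame
    manifest: dict
    errors: list = field(default_factory=list)


def _load_entry(entry: dict) -> pd.DataFrame:
    if "table" in entry:
        return entry["table"]
    return read_sumstats(entry["path"])


def _pair_seed(base: int, *idx: int) -> int:
    return int(np.random.SeedSequence([int(base), *map(int, idx)]).generate_state(1)[0])


def _result_fields(res: estimators.MRResult, prefix: str, binary: bool) -> dict:
    row = {
        f"{prefix}_estimate": res.estimate,
        f"{prefix}_ci_low": res.ci_low,
        f"{prefix}_ci_high": res.ci_high,
        f"{prefix}_pval": res.pval,
    }
    if binary:
        ors = res.or_scale()
        row[f"{prefix}_or"] = ors["or"]
        row[f"{prefix}_or_ci_low"] = ors["ci_low"]
        row[f"{prefix}_or_ci_high"] = ors["ci_high"]
    return row


def run_pipeline(config, out_dir=None) -> PipelineReport:
    """Run instruments -> harmonize -> estimators -> PRESSO -> classification
    for every exposure x outcome pair, plus optional MVMR/mediation loops.

    ``config`` is a dict or a path to a YAML file; table entries carry
    either ``path`` (TSV) or an in-memory ``table``. Failures are recorded
    per pair and the pipeline continues. With ``out_dir`` the report tables,
    forest-plot data and a JSON manifest are written as text files.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    seed = int(config.get("seed", 0))
    p_threshold = float(config.get("p_threshold", instr.GWAS_P_THRESHOLD))
    clump_r2 = float(config.get("clump_r2", 0.01))
    window_kb = float(config.get("window_kb", 10_000))
    maf_threshold = float(config.get("maf_threshold", 0.42))
    alpha = float(config.get("alpha", 0.05))
    n_boot = int(config.get("n_boot", 5000))
    presso_nsim = int(config.get("presso_nsim", 1000))

    exposures = config["exposures"]
    outcomes = config["outcomes"]
    mediators = config.get("mediators", [])
    ld = read_ld(config["ld"]) if config.get("ld") else None
    proxy = read_ld(config["proxy"]) if config.get("proxy") else None

    exp_tables = {e["name"]: _load_entry(e) for e in exposures}
    out_tables = {o["name"]: _load_entry(o) for o in outcomes}
    med_tables = {m["name"]: _load_entry(m) for m in mediators}

    primary_rows, forest_rows, errors = [], [], []
    ivw_cache: dict = {}

    for i, exp in enumerate(exposures):
        exp_table = exp_tables[exp["name"]]
        inst = instr.filter_significant(exp_table, p_threshold)
        inst = instr.ld_clump(inst, ld, clump_r2, window_kb)
        for j, out in enumerate(outcomes):
            pair = (exp["name"], out["name"])
            binary = bool(out.get("binary", False))
            try:
                out_table = out_tables[out["name"]]
                sel = inst.table
                missing = [s for s in sel["snp"] if s not in set(out_table["snp"])]
                proxied = {}
                if missing and proxy is not None:
                    mapping = instr.substitute_proxies(missing, proxy)
                    exp_all = exp_table.set_index("snp")
                    out_ids = set(out_table["snp"])
                    for orig, prox in mapping.items():
                        if prox in exp_all.index and prox in out_ids:
                            proxied[orig] = prox
                    if proxied:
                        sel = pd.concat(
                            [
                                sel.loc[~sel["snp"].isin(proxied)],
                                exp_table.loc[exp_table["snp"].isin(proxied.values())],
                            ],
                            ignore_index=True,
                        )
                hset = _harmonize(sel, out_table, maf_threshold)
                n_snp = len(hset)
                if n_snp < 2:
                    raise ValueError(f"only {n_snp} harmonized SNPs")
                pseed = _pair_seed(seed, i, j)

                res_ivw = estimators.ivw(hset)
                ivw_cache[pair] = (res_ivw, hset, sel)
                row = {
                    "exposure": exp["name"],
                    "outcome": out["name"],
                    "n_snp": n_snp,
                    "binary": binary,
                    "q": res_ivw.q,
                    "q_pval": res_ivw.q_pval,
                    "i2": res_ivw.i2,
                    "p": res_ivw.pval,
                }
                row.update(_result_fields(res_ivw, "ivw", binary))
                if n_snp >= 3:
                    egger = estimators.mr_egger(hset)
                    row.update(_result_fields(egger, "egger", binary))
                    row["egger_intercept"] = egger.egger_intercept
                    row["egger_intercept_pval"] = egger.intercept_pval
                    wm = estimators.weighted_median(hset, n_boot=n_boot, seed=pseed)
                    row.update(_result_fields(wm, "wmedian", binary))
                ml = estimators.max_likelihood(hset)
                row.update(_result_fields(ml, "ml", binary))
                if n_snp >= 4:
                    pres = mr_presso.presso(
                        hset, n_sim=presso_nsim, seed=pseed, effects="multiplicative_random"
                    )
                    row["presso_global_pval"] = pres.global_pval
                    row["presso_outliers"] = ",".join(pres.outlier_ids)
                    row.update(
                        _result_fields(pres.corrected_estimate, "ivw_corrected", binary)
                    )
                primary_rows.append(row)

                ratios = hset.data["beta_y"] / hset.data["beta_x"]
                ses = hset.data["se_y"] / hset.data["beta_x"].abs()
                for snp, r, s in zip(hset.data["snp"], ratios, ses):
                    forest_rows.append(
                        {
                            "exposure": exp["name"],
                            "outcome": out["name"],
                            "snp": snp,
                            "estimate": r,
                            "ci_low": r - estimators.Z95 * s,
                            "ci_high": r + estimators.Z95 * s,
                        }
                    )
            except Exception as exc:  # continue over remaining pairs
                errors.append({"exposure": pair[0], "outcome": pair[1], "error": str(exc)})

    primary = pd.DataFrame(primary_rows)
    if len(primary):
        primary = bonferroni_classify(
            primary,
            n_exposures=len(exposures),
            n_outcomes=len(outcomes),
            alpha=alpha,
        )

    mvmr_rows, mediation_rows = [], []
    for exp in exposures:
        for out in outcomes:
            pair = (exp["name"], out["name"])
            if pair not in ivw_cache:
                continue
            total, _, sel = ivw_cache[pair]
            out_table = out_tables[out["name"]]
            exp_table = exp_tables[exp["name"]]
            for med in mediators:  # one mediator at a time (default loop)
                try:
                    med_table = med_tables[med["name"]]
                    m_inst = instr.ld_clump(
                        instr.filter_significant(med_table, p_threshold),
                        ld,
                        clump_r2,
                        window_kb,
                    )
                    union = pd.concat(
                        [sel, exp_table.loc[exp_table["snp"].isin(m_inst.snps)]],
                        ignore_index=True,
                    ).drop_duplicates(subset="snp", keep="first")
                    union = instr.ld_clump(union, ld, clump_r2, window_kb).table
                    hm = _harmonize(union, med_table, maf_threshold)
                    hy = _harmonize(union, out_table, maf_threshold)
                    common = sorted(
                        set(hm.data["snp"]) & set(hy.data["snp"]),
                        key=list(union["snp"]).index,
                    )
                    dm = hm.data.set_index("snp").loc[common]
                    dy = hy.data.set_index("snp").loc[common]
                    inp = mm.MVMRInput(
                        snps=common,
                        beta_x=np.column_stack([dy["beta_x"], dm["beta_y"]]),
                        se_x=np.column_stack([dy["se_x"], dm["se_y"]]),
                        beta_y=dy["beta_y"].to_numpy(),
                        se_y=dy["se_y"].to_numpy(),
                        exposure_names=[exp["name"], med["name"]],
                    )
                    direct = mm.mvmr(inp)[0]
                    mvmr_rows.append(
                        {
                            "exposure": exp["name"],
                            "outcome": out["name"],
                            "adjusted_for": med["name"],
                            "n_snp": direct.n_snp,
                            **_result_fields(direct, "direct", bool(out.get("binary", False))),
                        }
                    )
                    medn = mm.mediate(total, direct, mediator_names=[med["name"]])
                    mediation_rows.append(
                        {
                            "exposure": exp["name"],
                            "outcome": out["name"],
                            "mediator": med["name"],
                            "es": medn.proportion_mediated,
                            "ci_low": medn.pm_ci_low,
                            "ci_high": medn.pm_ci_high,
                            "indirect": medn.indirect_estimate,
                            "indirect_se": medn.indirect_se,
                        }
                    )
                except Exception as exc:
                    errors.append(
                        {
                            "exposure": pair[0],
                            "outcome": pair[1],
                            "mediator": med["name"],
                            "error": str(exc),
                        }
                    )

    manifest = {
        "seed": seed,
        "p_threshold": p_threshold,
        "clump_r2": clump_r2,
        "window_kb": window_kb,
        "maf_threshold": maf_threshold,
        "alpha": alpha,
        "bonferroni_threshold": alpha / max(1, len(exposures) * len(outcomes)),
        "n_boot": n_boot,
        "presso_nsim": presso_nsim,
        "exposures": [e["name"] for e in exposures],
        "outcomes": [o["name"] for o in outcomes],
        "mediators": [m["name"] for m in mediators],
        "n_primary_rows": len(primary_rows),
        "n_errors": len(errors),
        "errors": errors,
    }

    report = PipelineReport(
        primary=primary,
        mvmr=pd.DataFrame(mvmr_rows),
        mediation=pd.DataFrame(mediation_rows),
        forest=pd.DataFrame(forest_rows),
        manifest=manifest,
        errors=errors,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = {"sep": "\t", "index": False, "float_format": "%.10g"}
    report.primary.to_csv(out / "results_primary.tsv", **kw)
    report.mvmr.to_csv(out / "results_mvmr.tsv", **kw)
    report.mediation.to_csv(out / "mediation.tsv", **kw)
    report.forest.to_csv(out / "forest.tsv", **kw)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
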