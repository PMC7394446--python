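"""Classical activity t-test baseline and method-comparison metrics.

The activity analysis is the traditional MPRA approach: each barcode
gets a DNA factor (mean depth-adjusted DNA count), each (barcode, RNA
sample) cell an activity log((RNA count / d_s) / DNA factor), and the
two alleles are compared with a Welch t-test followed by
Benjamini-Hochberg correction across the assay.

Evaluation against simulated truth uses the ranking statistic of each
method (lower = stronger): AUC, AUPR, the standard deviation of effect
estimates over truly null variants ("spread at zero"), and the Pearson
correlation of estimates with the truth over functional variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .inference import AssayResult, FitConfig, fit_assay
from .io import CountTable, compute_depth_factors
from .simulate import SimTruth

__all__ = ["MethodResult", "EvalReport", "activity_ttest", "evaluate", "compare_methods"]


@dataclass
class MethodResult:
    """Per-variant estimates of one analysis method.

    ``frame`` columns: variant_id, effect (TS scale), stat (ranking
    statistic, lower = stronger, NaN = missing), call (bool).
    """

    frame: pd.DataFrame
    method: str


@dataclass
class EvalReport:
    method: str
    auc: float
    aupr: float
    spread_at_zero: float
    cor_functional: float

    def as_rows(self, sim_id: str = "") -> list:
        return [
            {"sim_id": sim_id, "method": self.method, "metric": k, "value": v}
            for k, v in [("auc", self.auc), ("aupr", self.aupr),
                         ("spread_at_zero", self.spread_at_zero),
                         ("cor_functional", self.cor_functional)]
        ]


def activity_ttest(
    table: CountTable,
    depths: pd.Series | None = None,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> MethodResult:
    """Activity-based Welch t-test with BH correction across variants.

    Zero RNA counts receive a pseudocount so their activity is defined;
    barcodes with zero DNA factor are dropped.  Variants with fewer
    than two usable activity values per allele are flagged missing.
    """
    if depths is None:
        depths = compute_depth_factors(table)
    dna_ids, rna_ids = table.dna_ids, table.rna_ids
    frame = table.frame
    d_dna = depths[dna_ids].to_numpy()
    d_rna = depths[rna_ids].to_numpy()

    dna_factor = (frame[dna_ids].to_numpy() / d_dna).mean(axis=1)
    rna_adj = frame[rna_ids].to_numpy(dtype=float)
    rna_adj[rna_adj == 0] = pseudocount
    rna_adj = rna_adj / d_rna

    usable = dna_factor > 0
    with np.errstate(divide="ignore"):
        acts = np.log(rna_adj / dna_factor[:, None])
    long = pd.DataFrame({
        "variant_id": np.repeat(frame["variant_id"].to_numpy()[usable], len(rna_ids)),
        "allele": np.repeat(frame["allele"].to_numpy()[usable], len(rna_ids)),
        "act": acts[usable].ravel(),
    })
    g = long.groupby(["variant_id", "allele"])["act"].agg(["count", "mean", "var"])
    stats_by = {
        a: g.xs(a, level="allele").reindex(sorted(frame["variant_id"].unique()))
        for a in ("ref", "alt")
    }
    n0, m0, v0 = (stats_by["ref"][c].to_numpy(dtype=float) for c in ("count", "mean", "var"))
    n1, m1, v1 = (stats_by["alt"][c].to_numpy(dtype=float) for c in ("count", "mean", "var"))
    ok = (n0 >= 2) & (n1 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        pval = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "variant_id": stats_by["ref"].index,
        "effect": np.where(ok, m1 - m0, np.nan),
        "stat": np.where(ok, pval, np.nan),
    })
    ok = out["stat"].notna()
    out["call"] = False
    if ok.any():
        rejected, _, _, _ = multipletests(out.loc[ok, "stat"], alpha=fdr, method="fdr_bh")
        out.loc[ok, "call"] = rejected
    return MethodResult(frame=out, method="ttest")


def bayes_method_result(assay: AssayResult, method: str = "nb-bayes") -> MethodResult:
    frame = assay.results.rename(
        columns={"ts_mean": "effect", "score": "stat", "functional_call": "call"}
    )[["variant_id", "effect", "stat", "call"]].copy()
    return MethodResult(frame=frame, method=method)


def evaluate(result: MethodResult, truth: SimTruth | pd.DataFrame) -> EvalReport:
    """Score one method against simulated truth.

    Variants missing from the results (or with missing statistics) are
    ranked least significant; without any functional variant in the
    truth, AUC/AUPR are reported as NaN.
    """
    tv = truth.variants if isinstance(truth, SimTruth) else truth
    merged = tv.merge(result.frame, on="variant_id", how="left")
    labels = merged["functional"].to_numpy(dtype=bool)

    stat = merged["stat"].to_numpy(dtype=float)
    worst = np.nanmax(stat) if np.isfinite(stat).any() else 1.0
    score = -np.where(np.isnan(stat), worst, stat)   # higher = stronger for sklearn

    if labels.any() and (~labels).any():
        auc = float(roc_auc_score(labels, score))
        aupr = float(average_precision_score(labels, score))
    else:
        auc = aupr = math.nan

    effect = merged["effect"].to_numpy(dtype=float)
    null_eff = effect[~labels & np.isfinite(effect)]
    spread = float(np.std(null_eff, ddof=1)) if null_eff.size >= 2 else math.nan
    fun = labels & np.isfinite(effect)
    if fun.sum() >= 3 and np.std(effect[fun]) > 0 and np.std(merged.loc[fun, "true_ts"]) > 0:
        cor = float(stats.pearsonr(effect[fun], merged.loc[fun, "true_ts"]).statistic)
    else:
        cor = math.nan
    return EvalReport(method=result.method, auc=auc, aupr=aupr,
                      spread_at_zero=spread, cor_functional=cor)


def compare_methods(
    table: CountTable,
    truth: SimTruth | None = None,
    methods=("bayes-marginal", "ttest"),
    cfg: FitConfig = FitConfig(),
    annotations=None,
) -> tuple[dict, pd.DataFrame]:
    """Run several in-package methods on one assay.

    Returns ({method: EvalReport or None}, Pearson correlation matrix of
    effect estimates).  Failures of individual methods are recorded as
    None and excluded from the matrix.
    """
    results: dict[str, MethodResult] = {}
    shared_mles = None
    for method in methods:
        try:
            if method == "ttest":
                results[method] = activity_ttest(table)
            elif method.startswith("bayes-"):
                mode = method.split("-", 1)[1]
                assay = fit_assay(table, priors=mode, cfg=cfg, annotations=annotations,
                                  mles=shared_mles)
                shared_mles = assay.mles
                results[method] = bayes_method_result(assay, method=method)
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:
            warnings.warn(f"method {method!r} failed: {exc}", stacklevel=2)

    reports = {m: (evaluate(r, truth) if truth is not None else None)
               for m, r in results.items()}

    names = list(results)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        fa = results[a].frame.set_index("variant_id")["effect"]
        for j, b_ in enumerate(names[i + 1:], start=i + 1):
            fb = results[b_].frame.set_index("variant_id")["effect"]
            joined = pd.concat([fa, fb], axis=1, keys=["a", "b"]).dropna()
            r = stats.pearsonr(joined["a"], joined["b"]).statistic if len(joined) >= 3 else np.nan
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return reports, corr
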