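"""Cross-cell-line differential-expression screen and PDK-isoform report.

Works on log2-scale expression matrices (genes x samples) with sample
annotations (model, condition, replicate).  Per model, the log2 fold-change
is the mean difference on the log2 scale and p-values come from a plain
two-sample Student t-test, Benjamini-Hochberg adjusted within the model
over all genes.  The consistency filter keeps genes with
|log2FC| > log2(threshold) and adjusted p below threshold in every model,
same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, SchemaError

PDK_FAMILY = ["PDK1", "PDK2", "PDK3", "PDK4"]


def _split_samples(samples: pd.DataFrame, model: str):
    sub = samples[samples["model"] == model]
    par = sub.loc[sub["condition"] == "parental", "sample"].tolist()
    mes = sub.loc[sub["condition"] == "mesenchymal", "sample"].tolist()
    if len(par) < 2 or len(mes) < 2:
        raise SchemaError(
            f"model {model!r}: need >= 2 replicates per condition "
            f"(parental {len(par)}, mesenchymal {len(mes)})"
        )
    return par, mes


def de_stats(matrix: pd.DataFrame, samples: pd.DataFrame, model: str) -> pd.DataFrame:
    """Per-gene log2 fold-change, Student-t p and BH-adjusted p for one model."""
    par_cols, mes_cols = _split_samples(samples, model)
    par = matrix[par_cols].to_numpy()
    mes = matrix[mes_cols].to_numpy()
    log2_fc = mes.mean(axis=1) - par.mean(axis=1)
    t, p = stats.ttest_ind(mes, par, axis=1, equal_var=True)
    var0 = (par.var(axis=1, ddof=1) == 0) & (mes.var(axis=1, ddof=1) == 0)
    p = np.where(var0 & np.isclose(log2_fc, 0.0), 1.0, p)
    p = np.where(var0 & ~np.isclose(log2_fc, 0.0), 0.0, p)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": p, "adj_p": adj_p}, index=matrix.index
    )


@dataclass(frozen=True)
class DEResult:
    """A gene passing the all-models expression consistency filter."""

    gene: str
    direction: str
    per_model: tuple  # ((model, log2_fc, p, adj_p), ...)
    mean_abs_log2_fc: float


def gene_consistency_filter(
    stats_by_model: dict[str, pd.DataFrame],
    fc_threshold: float = 5.0,
    adjp_threshold: float = 1e-5,
) -> list[DEResult]:
    """Genes with |FC| beyond threshold and FDR below threshold in every model.

    The fold-change gate is applied on the anti-logged scale:
    |log2_fc| > log2(fc_threshold).  Direction must agree across models.
    Result sorted by mean |log2FC| descending.
    """
    if fc_threshold <= 1 or not 0 < adjp_threshold <= 1:
        raise InvalidParameterError("fc_threshold must be > 1 and adjp in (0, 1]")
    if not stats_by_model:
        raise InvalidParameterError("need at least one model")
    models = sorted(stats_by_model)
    lfc_gate = np.log2(fc_threshold)
    common = set.intersection(*(set(df.index) for df in stats_by_model.values()))
    results = []
    for gene in common:
        rows = [(m, stats_by_model[m].loc[gene]) for m in models]
        ok = all(
            abs(r["log2_fc"]) > lfc_gate and r["adj_p"] < adjp_threshold for _, r in rows
        )
        if not ok:
            continue
        signs = {np.sign(r["log2_fc"]) for _, r in rows}
        if len(signs) > 1:
            continue
        results.append(
            DEResult(
                gene=gene,
                direction="up" if signs.pop() > 0 else "down",
                per_model=tuple(
                    (m, float(r["log2_fc"]), float(r["p_value"]), float(r["adj_p"]))
                    for m, r in rows
                ),
                mean_abs_log2_fc=float(np.mean([abs(r["log2_fc"]) for _, r in rows])),
            )
        )
    results.sort(key=lambda r: (-r.mean_abs_log2_fc, r.gene))
    return results


def annotate_metabolic(hits: list[DEResult], metabolism_gene_set: list[str]) -> list[DEResult]:
    """Subset of hits in the metabolism gene set, ordered by mean |log2FC|."""
    gene_set = set(metabolism_gene_set)
    return [h for h in hits if h.gene in gene_set]


def isoform_report(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    family: list[str] | None = None,
    fc_threshold: float = 5.0,
    adjp_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Per-model fold-change table for a gene family (PDK1..PDK4 by default).

    Rows: (gene, model) with log2_fc, p, adj_p and a ``flagged`` column
    marking genes that meet the full consistency filter.  Missing family
    members trigger a warning and are reported as the available subset.
    """
    if family is None:
        family = PDK_FAMILY
    present = [g for g in family if g in matrix.index]
    missing = [g for g in family if g not in matrix.index]
    if missing:
        warnings.warn(f"family members missing from matrix: {missing}")
    if not present:
        raise SchemaError("no family members present in the expression matrix")
    models = sorted(samples["model"].unique())
    stats_by_model = {m: de_stats(matrix, samples, m) for m in models}
    flagged_genes = {
        h.gene
        for h in gene_consistency_filter(stats_by_model, fc_threshold, adjp_threshold)
        if h.gene in present
    }
    rows = []
    for gene in present:
        for model in models:
            r = stats_by_model[model].loc[gene]
            rows.append(
                {
                    "gene": gene,
                    "model": model,
                    "log2_fc": float(r["log2_fc"]),
                    "p_value": float(r["p_value"]),
                    "adj_p": float(r["adj_p"]),
                    "flagged": gene in flagged_genes,
                }
            )
    return pd.DataFrame(rows)
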