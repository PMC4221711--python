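"""Cross-cell-line differential-metabolite screen.

Per cell-line model, each metabolite is compared between the parental and
mesenchymal conditions with a two-sample Student t-test on raw abundances,
and the fold-change mean(mesenchymal)/mean(parental) is recorded.  The
consistency filter then keeps metabolites whose absolute fold-change
exceeds a threshold (FC > 2 or FC < 1/2, by default) with p below a
threshold in EVERY model, in the same direction.  The amino-acid panel
summarises log2 fold-changes of the 20 standard amino acids across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, SchemaError
from .simulate import TWENTY_AMINO_ACIDS

REQUIRED_COLUMNS = {"metabolite", "super_pathway", "model", "condition", "replicate", "abundance"}


@dataclass(frozen=True)
class ScreenHit:
    """A metabolite passing the all-models consistency filter."""

    metabolite: str
    direction: str  # 'up' or 'down' in mesenchymal vs parental
    per_model: tuple  # ((model, fold_change, p_value), ...)


def _validate(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise SchemaError(f"abundance table missing columns: {sorted(missing)}")


def _group_stats(table: pd.DataFrame, model: str, value_col: str, welch: bool):
    """Vectorised per-metabolite t-test for one model. Returns a DataFrame."""
    sub = table[table["model"] == model]
    conds = set(sub["condition"].unique())
    if not {"parental", "mesenchymal"} <= conds:
        raise SchemaError(f"model {model!r} lacks both conditions (has {sorted(conds)})")
    piv = sub.pivot_table(
        index="metabolite", columns=["condition", "replicate"], values=value_col
    )
    par = piv["parental"].to_numpy()
    mes = piv["mesenchymal"].to_numpy()
    if par.shape[1] < 2 or mes.shape[1] < 2:
        raise SchemaError(f"model {model!r}: need >= 2 replicates per condition")
    mean_p = par.mean(axis=1)
    mean_m = mes.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_m / mean_p
    t, p = stats.ttest_ind(mes, par, axis=1, equal_var=not welch)
    # degenerate rows: zero variance in both groups
    var0 = (par.var(axis=1, ddof=1) == 0) & (mes.var(axis=1, ddof=1) == 0)
    equal = np.isclose(mean_p, mean_m)
    p = np.where(var0 & equal, 1.0, p)
    t = np.where(var0 & equal, 0.0, t)
    p = np.where(var0 & ~equal, 0.0, p)
    return pd.DataFrame(
        {
            "metabolite": piv.index,
            "fold_change": fc,
            "p_value": p,
            "t_stat": t,
            "zero_parental": mean_p == 0,
        }
    ).set_index("metabolite")


def per_model_stats(
    table: pd.DataFrame, model: str, welch: bool = False, log_scale: bool = False
) -> pd.DataFrame:
    """Fold-change and Student-t p per metabolite for one cell-line model.

    Metabolites with an all-zero parental condition get fold_change = inf
    and are flagged via the ``zero_parental`` column rather than dropped.
    ``log_scale=True`` runs the t-test on log abundances (FC still on the
    raw-mean scale).
    """
    _validate(table)
    if model not in set(table["model"]):
        raise SchemaError(f"model {model!r} not present in table")
    if log_scale:
        table = table.copy()
        table["_log"] = np.log(table["abundance"].clip(lower=1e-12))
        out = _group_stats(table, model, "_log", welch)
        raw = _group_stats(table, model, "abundance", welch)
        out["fold_change"] = raw["fold_change"]
        out["zero_parental"] = raw["zero_parental"]
        return out
    return _group_stats(table, model, "abundance", welch)


def consistency_filter(
    stats_by_model: dict[str, pd.DataFrame],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    require_same_direction: bool = True,
) -> list[ScreenHit]:
    """Metabolites significant with |FC| beyond threshold in every model.

    "Absolute fold-change > T" is read two-sided: FC > T or FC < 1/T.
    With ``require_same_direction`` the direction must agree across models.
    Metabolites flagged zero_parental in any model are excluded from the
    ranking (their FC is undefined).
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise InvalidParameterError("thresholds must be positive")
    if not stats_by_model:
        raise InvalidParameterError("need at least one model")
    models = sorted(stats_by_model)
    common = set.intersection(*(set(df.index) for df in stats_by_model.values()))
    hits = []
    for met in sorted(common):
        rows = [(m, stats_by_model[m].loc[met]) for m in models]
        if any(r["zero_parental"] for _, r in rows):
            continue
        ok = all(
            (r["fold_change"] > fc_threshold or r["fold_change"] < 1.0 / fc_threshold)
            and r["p_value"] < p_threshold
            for _, r in rows
        )
        if not ok:
            continue
        dirs = {"up" if r["fold_change"] > 1 else "down" for _, r in rows}
        if require_same_direction and len(dirs) > 1:
            continue
        hits.append(
            ScreenHit(
                metabolite=met,
                direction=dirs.pop() if len(dirs) == 1 else "mixed",
                per_model=tuple(
                    (m, float(r["fold_change"]), float(r["p_value"])) for m, r in rows
                ),
            )
        )
    return hits


def category_summary(hits: list[ScreenHit], annotations: pd.DataFrame | dict) -> dict:
    """Count hits per super-pathway; amino-acid + peptide also reported jointly.

    ``annotations`` maps metabolite -> super_pathway (dict, or a table with
    those columns).  Unannotated hits are bucketed as 'unannotated'.
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = (
            annotations.drop_duplicates("metabolite")
            .set_index("metabolite")["super_pathway"]
            .to_dict()
        )
    counts: dict[str, int] = {}
    for h in hits:
        cat = annotations.get(h.metabolite, "unannotated")
        counts[cat] = counts.get(cat, 0) + 1
    counts["amino acid + peptide"] = counts.get("amino acid", 0) + counts.get("peptide", 0)
    if not hits:
        return {}
    return counts


def amino_acid_panel(
    table: pd.DataFrame, aa_list: list[str] | None = None, welch: bool = False
) -> dict:
    """Per-model log2 fold-change matrix for the standard amino acids.

    Returns {'log2_fc': DataFrame (amino acid x model),
             'fraction_increased': fraction of (aa, model) cells with FC > 1,
             'missing': amino acids absent from the table}.
    Ties (FC == 1) count as not increased.
    """
    import warnings

    _validate(table)
    if aa_list is None:
        aa_list = TWENTY_AMINO_ACIDS
    present = [a for a in aa_list if a in set(table["metabolite"])]
    missing = [a for a in aa_list if a not in present]
    if len(present) < 15:
        warnings.warn(f"only {len(present)} of {len(aa_list)} amino acids present")
    models = sorted(table["model"].unique())
    fc = pd.DataFrame(index=present, columns=models, dtype=float)
    for model in models:
        st = per_model_stats(table, model, welch=welch)
        for aa in present:
            fc.loc[aa, model] = np.log2(st.loc[aa, "fold_change"])
    increased = (fc > 0).to_numpy().sum()
    return {
        "log2_fc": fc,
        "fraction_increased": float(increased) / fc.size if fc.size else 0.0,
        "missing": missing,
    }
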