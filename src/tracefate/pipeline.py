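"""End-to-end orchestration: validate -> simulate -> analyze -> report.

``run_all`` drives the full demo loop on synthetic inputs generated from a
single root seed: tracer-labelling MID statistics for the parental and
mesenchymal presets, Seahorse PPR/OCR comparison, flux-parameter recovery,
the metabolite and gene consistency screens, and the survival
meta-analysis.  Every output is a UTF-8 CSV re-readable by the stage that
would consume it, plus a JSON run manifest recording seed, thresholds,
package version and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .isotope import (
    DEFAULT_P13,
    COMPOUNDS,
    CompoundSpec,
    RawIntensityVector,
    correct_natural_abundance,
    glycolysis_oxphos_ratio,
    recover_flux_params,
    student_t_compare,
    MID,
)
from .metabolomics import (
    amino_acid_panel,
    category_summary,
    consistency_filter,
    per_model_stats,
)
from .simulate import (
    PRESETS,
    ExpressionData,
    ScreenDesign,
    SurvivalSpec,
    simulate_expression,
    simulate_metabolomics,
    simulate_seahorse_wells,
    simulate_survival_cohorts,
    simulate_tracer_labeling,
)
from .survival import cox_by_median_split, meta_fixed
from .transcriptomics import de_stats, gene_consistency_filter, isoform_report

logger = logging.getLogger("tracefate")

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds, seed and output location for a full pipeline run."""

    seed: int = 0
    out_dir: str = "tracefate_out"
    p13: float = DEFAULT_P13
    correction_method: str = "nnls"
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    gene_fc_threshold: float = 5.0
    gene_adjp_threshold: float = 1e-5
    meta_model: str = "fixed"
    n_tracer_replicates: int = 5
    noise_cv: float = 0.05
    metabolomics: ScreenDesign = field(
        default_factory=lambda: ScreenDesign(
            n_models=3, n_replicates=5, n_features=400,
            planted_effects={"glutamine": 3.0, "tryptophan": 2.5, "met0000": 0.25},
            sigma=0.25,
        )
    )
    # 5 replicates/condition: with a plain (unmoderated) Student t at the
    # microarray design's 3 replicates, df=4 tail mass caps BH-adjusted p
    # well above the 1e-5 gate for any realistic sigma, so the synthetic
    # world uses 5 to make the planted PDK4 effect detectable.
    expression: ScreenDesign = field(
        default_factory=lambda: ScreenDesign(
            n_models=3, n_replicates=5, n_features=2000,
            planted_effects={"PDK4": 1.0 / 8.0}, sigma=0.15,
        )
    )
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "metabolomics":
                kwargs[key] = ScreenDesign(**value)
            elif key == "expression":
                kwargs[key] = ScreenDesign(**value)
            elif key == "survival":
                kwargs[key] = SurvivalSpec(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

SCHEMAS = {
    "tracer_long": {
        "columns": ["compound", "n_carbons", "sample", "condition", "replicate",
                     "tracer", "mass_shift", "intensity"],
        "row_checks": [("intensity", lambda v: v >= 0, "negative intensity")],
    },
    "metabolomics_long": {
        "columns": ["metabolite", "super_pathway", "model", "condition",
                     "replicate", "abundance"],
        "row_checks": [("abundance", lambda v: v >= 0, "negative abundance")],
    },
    "survival_cohort": {
        "columns": ["patient_id", "time", "event", "expression"],
        "row_checks": [
            ("time", lambda v: v > 0, "non-positive survival time"),
            ("event", lambda v: v in (0, 1), "event flag not 0/1"),
        ],
    },
}


def validate_inputs(paths: dict[str, str | Path], schemas: dict = None) -> dict:
    """Per-file schema validation with row-level messages.

    ``paths`` maps schema name -> CSV/TSV path.  Returns
    {path: {'ok': bool, 'messages': [...]}}; the pipeline refuses to run on
    any failure.
    """
    schemas = schemas or SCHEMAS
    report = {}
    for schema_name, path in paths.items():
        path = Path(path)
        messages: list[str] = []
        schema = schemas.get(schema_name)
        if schema is None:
            messages.append(f"unknown schema {schema_name!r}")
            report[str(path)] = {"ok": False, "messages": messages}
            continue
        try:
            sep = "\t" if path.suffix in (".tsv", ".tab") else ","
            df = pd.read_csv(path, sep=sep)
        except OSError as exc:
            raise OSError(f"cannot read {path}: {exc}") from exc
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            messages.append(f"missing columns: {missing}")
        else:
            for col, check, label in schema.get("row_checks", []):
                bad = [i for i, v in enumerate(df[col]) if not check(v)]
                for i in bad[:20]:
                    messages.append(f"row {i}: {label} ({col}={df[col].iloc[i]!r})")
        report[str(path)] = {"ok": not messages, "messages": messages}
    return report


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def analyze_tracer_table(
    table: pd.DataFrame, p13: float = DEFAULT_P13, method: str = "nnls"
) -> tuple[pd.DataFrame, dict]:
    """Correct every (compound, sample) intensity vector and summarise per condition.

    Returns (tidy stats DataFrame with columns compound, condition, tracer, k,
    fraction_mean, fraction_sem, p_value; dict of per-sample corrected MIDs
    keyed by (compound, sample)).
    """
    required = set(SCHEMAS["tracer_long"]["columns"])
    if not required <= set(table.columns):
        raise SchemaError(f"tracer table missing {sorted(required - set(table.columns))}")
    mids: dict[tuple, MID] = {}
    frac_rows = []
    for (compound, sample), grp in table.groupby(["compound", "sample"], sort=True):
        n = int(grp["n_carbons"].iloc[0])
        grp = grp.sort_values("mass_shift")
        raw = RawIntensityVector(
            compound=CompoundSpec(compound, n),
            sample_id=str(sample),
            intensities=grp["intensity"].to_numpy(),
        )
        mid = correct_natural_abundance(raw, p13=p13, method=method)
        mids[(compound, sample)] = mid
        cond = grp["condition"].iloc[0]
        tracer = grp["tracer"].iloc[0]
        for k, frac in enumerate(mid.fractions):
            frac_rows.append(
                {"compound": compound, "condition": cond, "tracer": tracer,
                 "sample": sample, "k": k, "fraction": frac}
            )
    fr = pd.DataFrame(frac_rows)
    out_rows = []
    for (compound, tracer, k), grp in fr.groupby(["compound", "tracer", "k"], sort=True):
        by_cond = {c: g["fraction"].to_numpy() for c, g in grp.groupby("condition")}
        conds = sorted(by_cond)
        p_value = np.nan
        if len(conds) == 2 and all(len(v) >= 2 for v in by_cond.values()):
            p_value = student_t_compare(by_cond[conds[0]], by_cond[conds[1]]).p_value
        for cond in conds:
            v = by_cond[cond]
            out_rows.append(
                {
                    "compound": compound, "condition": cond, "tracer": tracer, "k": k,
                    "fraction_mean": float(np.mean(v)),
                    "fraction_sem": float(np.std(v, ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1 else 0.0,
                    "p_value": p_value,
                }
            )
    return pd.DataFrame(out_rows), mids


def _mean_mid(mids: dict, compound: str, condition: str, tracer: str) -> MID:
    """Average corrected MID over the replicates of one (condition, tracer) arm."""
    prefix = f"{condition}_{tracer}_"
    stack = [
        m.fractions
        for (c, s), m in mids.items()
        if c == compound and s.startswith(prefix)
    ]
    mean = np.mean(stack, axis=0)
    return MID(compound=COMPOUNDS[compound], fractions=mean / mean.sum())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> dict:
    """Full simulate -> analyze -> report loop; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rootseed = int(config.seed) % (2**31 - 1000)
    logger.info("run_all seed=%d out=%s", rootseed, out)

    # --- stage 1: tracer labelling -> corrected MID statistics ------------
    tables = []
    for i, (cond, preset) in enumerate(sorted(PRESETS.items())):
        params = preset.__class__(**{**asdict(preset), "noise_cv": config.noise_cv})
        for j, tracer in enumerate(("glucose", "glutamine")):
            tables.append(
                simulate_tracer_labeling(
                    params, tracer, cond, config.n_tracer_replicates,
                    seed=rootseed + 10 * i + j, p13=config.p13,
                )
            )
    tracer_table = pd.concat(tables, ignore_index=True)
    _write_csv(tracer_table, out / "tracer_input.csv")
    mid_stats, mids = analyze_tracer_table(tracer_table, config.p13, config.correction_method)
    _write_csv(mid_stats, out / "mid_statistics.csv")

    # flux-parameter recovery per condition from the mean corrected MIDs
    rec_rows = []
    for cond in sorted(PRESETS):
        rec = recover_flux_params(
            _mean_mid(mids, "pyruvate", cond, "glucose"),
            _mean_mid(mids, "glutamate", cond, "glucose"),
            _mean_mid(mids, "glutamate", cond, "glutamine"),
        )
        rec_rows.append({"condition": cond, "g_pdh": rec.g_pdh,
                         "f_pyr": rec.f_pyr, "q_gln": rec.q_gln})
    _write_csv(pd.DataFrame(rec_rows), out / "flux_recovery.csv")

    # --- stage 2: Seahorse PPR/OCR ----------------------------------------
    wells = []
    for i, (cond, preset) in enumerate(sorted(PRESETS.items())):
        wells += simulate_seahorse_wells(preset, cond, n_wells=6, seed=rootseed + 100 + i)
    sea = glycolysis_oxphos_ratio(wells)
    sea_rows = [
        {"condition": cond, "ppr_ocr_mean": m, "ppr_ocr_sem": s, "n_wells": n,
         "p_value": sea["comparison"].p_value if sea["comparison"] else np.nan}
        for cond, (m, s, n) in sorted(sea["per_condition"].items())
    ]
    _write_csv(pd.DataFrame(sea_rows), out / "seahorse.csv")

    # --- stage 3: metabolomics screen -------------------------------------
    met = simulate_metabolomics(config.metabolomics, seed=rootseed + 200)
    _write_csv(met, out / "metabolomics_input.csv")
    stats_by_model = {
        m: per_model_stats(met, m) for m in sorted(met["model"].unique())
    }
    hits = consistency_filter(stats_by_model, config.fc_threshold, config.p_threshold)
    hit_rows = [
        {"metabolite": h.metabolite, "direction": h.direction,
         **{f"{m}_fc": fc for m, fc, _ in h.per_model},
         **{f"{m}_p": p for m, _, p in h.per_model}}
        for h in hits
    ]
    _write_csv(pd.DataFrame(hit_rows), out / "metabolite_hits.csv")
    cats = category_summary(hits, met[["metabolite", "super_pathway"]])
    (out / "category_summary.json").write_text(json.dumps(cats, indent=2, sort_keys=True))
    panel = amino_acid_panel(met)
    panel_df = panel["log2_fc"].reset_index(names="amino_acid")
    panel_df["fraction_increased"] = panel["fraction_increased"]
    _write_csv(panel_df, out / "amino_acid_panel.csv")

    # --- stage 4: expression screen ---------------------------------------
    expr = simulate_expression(config.expression, seed=rootseed + 300)
    expr.matrix.to_csv(out / "expression_matrix.csv", float_format="%.10g",
                       lineterminator="\n")
    _write_csv(expr.samples, out / "expression_samples.csv")
    de_by_model = {
        m: de_stats(expr.matrix, expr.samples, m)
        for m in sorted(expr.samples["model"].unique())
    }
    gene_hits = gene_consistency_filter(
        de_by_model, config.gene_fc_threshold, config.gene_adjp_threshold
    )
    gh_rows = [
        {"gene": h.gene, "direction": h.direction,
         "mean_abs_log2_fc": h.mean_abs_log2_fc}
        for h in gene_hits
    ]
    _write_csv(pd.DataFrame(gh_rows), out / "gene_hits.csv")
    iso = isoform_report(expr.matrix, expr.samples,
                         fc_threshold=config.gene_fc_threshold,
                         adjp_threshold=config.gene_adjp_threshold)
    _write_csv(iso, out / "isoform_report.csv")

    # --- stage 5: survival meta-analysis ----------------------------------
    cohorts = simulate_survival_cohorts(config.survival, seed=rootseed + 400)
    cox_results = []
    forest_rows = []
    for cohort in cohorts:
        _write_csv(cohort, out / f"survival_{cohort['cohort'].iloc[0]}.csv")
        res = cox_by_median_split(cohort["time"], cohort["event"], cohort["expression"])
        cox_results.append(res)
        forest_rows.append(
            {"study": cohort["cohort"].iloc[0], "hr": res.hr,
             "ci_low": float(np.exp(res.log_hr - 1.96 * res.se)),
             "ci_high": float(np.exp(res.log_hr + 1.96 * res.se)),
             "log_hr": res.log_hr, "se": res.se, "p": res.p,
             "n_events": res.n_events, "weight": 1.0 / res.se**2}
        )
    meta = meta_fixed(cox_results, random_effects=(config.meta_model == "random"))
    forest_rows.append(
        {"study": "combined", "hr": meta.hr, "ci_low": meta.hr_ci95[0],
         "ci_high": meta.hr_ci95[1], "log_hr": meta.combined_log_hr,
         "se": meta.combined_se, "p": meta.p,
         "n_events": sum(r.n_events for r in cox_results),
         "weight": sum(1.0 / r.se**2 for r in cox_results)}
    )
    _write_csv(pd.DataFrame(forest_rows), out / "survival_forest.csv")

    # --- manifest ----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": rootseed,
        "thresholds": {
            "p13": config.p13, "fc": config.fc_threshold, "p": config.p_threshold,
            "gene_fc": config.gene_fc_threshold, "gene_adjp": config.gene_adjp_threshold,
        },
        "meta_model": config.meta_model,
        "inputs": {
            f.name: _sha256(f)
            for f in sorted(out.glob("*input*.csv"))
        },
        "outputs": sorted(f.name for f in out.glob("*.csv")),
        "summary": {
            "n_metabolite_hits": len(hits),
            "n_gene_hits": len(gene_hits),
            "meta_log_hr": meta.combined_log_hr,
            "meta_p": meta.p,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
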