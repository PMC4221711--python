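"""Synthetic-data generators with known ground truth for every pipeline stage.

Five generators emulate the five input classes the analysis consumes:

* a first-turn TCA labelling model producing raw isotopologue intensity
  tables under U-13C6 glucose or U-13C5 glutamine tracers, with
  natural-abundance convolution and multiplicative measurement noise;
* lognormal metabolite abundance tables with fold-changes planted
  consistently (or not) across cell-line models;
* log2-scale expression matrices with planted |FC| effects and the PDK
  isoform family included by name;
* Seahorse-style PPR/OCR wells;
* exponential survival cohorts with a group-dependent hazard and uniform
  exponential censoring.

The labelling model is deliberately first-turn only: species downstream of
citrate appear at M+0 or M+2 (acetyl-unit entry via PDH), matching the
readouts the analysis computes; multi-turn M+4 species and anaplerotic
(pyruvate-carboxylase) M+3 citrate are omitted.

All randomness flows through a seeded ``numpy.random.Generator``, so equal
seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .isotope import (
    COMPOUNDS,
    DEFAULT_P13,
    FluxParams,
    SeahorseMeasurement,
    build_correction_matrix,
)

# Presets chosen so the qualitative pattern of an epithelial->mesenchymal
# transition emerges by default: mesenchymal cells route more pyruvate into
# the TCA cycle (higher g_pdh) and run a lower glycolysis/OXPHOS ratio.
# These are illustrative presets, not measured values.
PRESETS = {
    "parental": FluxParams(f_pyr=0.8, g_pdh=0.3, q_gln=0.7, ppr_true=100.0, ocr_true=50.0),
    "mesenchymal": FluxParams(f_pyr=0.8, g_pdh=0.6, q_gln=0.5, ppr_true=100.0, ocr_true=100.0),
}

TWENTY_AMINO_ACIDS = [
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
]


# ---------------------------------------------------------------------------
# Tracer labelling
# ---------------------------------------------------------------------------


def true_mids(params: FluxParams, tracer: str) -> dict[str, np.ndarray]:
    """Noise-free MIDs implied by the first-turn model for one tracer.

    Glucose tracer: pyruvate M+3 = f_pyr; lactate M+3 = f_pyr*(1-d_lac);
    citrate/aKG/malate M+2 = g_pdh*f_pyr; glutamate M+2 =
    g_pdh*f_pyr*(1-q_gln); remaining mass at M+0.  Glutamine tracer:
    glutamate M+5 = q_gln; everything else unlabelled.
    """
    if tracer not in ("glucose", "glutamine"):
        raise InvalidParameterError(f"unknown tracer {tracer!r}")
    mids: dict[str, np.ndarray] = {}
    for name, spec in COMPOUNDS.items():
        v = np.zeros(spec.n_carbons + 1)
        if tracer == "glucose":
            if name == "pyruvate":
                v[3] = params.f_pyr
            elif name == "lactate":
                v[3] = params.f_pyr * (1.0 - params.d_lac)
            elif name in ("citrate", "alpha-ketoglutarate", "malate"):
                v[2] = params.g_pdh * params.f_pyr
            elif name == "glutamate":
                v[2] = params.g_pdh * params.f_pyr * (1.0 - params.q_gln)
        else:  # glutamine tracer
            if name == "glutamate":
                v[5] = params.q_gln
        v[0] = 1.0 - v[1:].sum()
        mids[name] = v
    return mids


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_tracer_labeling(
    params: FluxParams,
    tracer: str,
    condition: str,
    n_replicates: int,
    seed: int,
    p13: float = DEFAULT_P13,
    abundance_scale: float = 1e6,
    abundance_sigma: float = 0.2,
) -> pd.DataFrame:
    """Raw isotopologue intensity table in the long format the MID stage reads.

    Each replicate's true MID is smeared with the natural-abundance matrix,
    scaled by a lognormal per-replicate abundance, perturbed with
    per-isotopologue multiplicative noise of CV ``params.noise_cv``, and
    floored at zero.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mids = true_mids(params, tracer)
    rows = []
    for name, x in mids.items():
        n = COMPOUNDS[name].n_carbons
        cm = build_correction_matrix(n, p13)
        observed = cm.entries @ x
        for rep in range(1, n_replicates + 1):
            scale = abundance_scale * rng.lognormal(0.0, abundance_sigma)
            noisy = observed * scale * _lognormal_factor(rng, params.noise_cv, n + 1)
            noisy = np.clip(noisy, 0.0, None)
            for k in range(n + 1):
                rows.append(
                    {
                        "compound": name,
                        "n_carbons": n,
                        "sample": f"{condition}_{tracer}_r{rep}",
                        "condition": condition,
                        "replicate": rep,
                        "tracer": tracer,
                        "mass_shift": k,
                        "intensity": noisy[k],
                    }
                )
    return pd.DataFrame(rows)


def simulate_seahorse_wells(
    params: FluxParams,
    condition: str,
    n_wells: int,
    seed: int,
    cv: float = 0.1,
) -> list[SeahorseMeasurement]:
    """Per-well PPR/OCR around the preset true rates with lognormal well noise."""
    if n_wells < 2:
        raise InvalidParameterError("need >= 2 wells")
    rng = np.random.default_rng(seed)
    wells = []
    for i in range(1, n_wells + 1):
        ppr = params.ppr_true * float(_lognormal_factor(rng, cv, 1)[0])
        ocr = params.ocr_true * float(_lognormal_factor(rng, cv, 1)[0])
        wells.append(
            SeahorseMeasurement(
                sample_id=f"{condition}_w{i}", condition=condition, ppr=ppr, ocr=ocr
            )
        )
    return wells


# ---------------------------------------------------------------------------
# Metabolomics / expression screens
# ---------------------------------------------------------------------------


@dataclass
class ScreenDesign:
    """Design of a cross-model differential screen with planted effects.

    ``planted_effects`` maps feature -> fold-change, applied in every model
    unless the feature also appears in ``model_restricted`` (then only in
    the listed models).  ``sigma`` is the lognormal log-scale SD of the
    replicate noise.
    """

    n_models: int = 3
    n_replicates: int = 5
    n_features: int = 400
    planted_effects: dict[str, float] = field(default_factory=dict)
    model_restricted: dict[str, list[str]] = field(default_factory=dict)
    sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise InvalidParameterError("n_replicates must be >= 2")
        if any(fc <= 0 for fc in self.planted_effects.values()):
            raise InvalidParameterError("planted fold-changes must be > 0")

    @property
    def models(self) -> list[str]:
        return [f"model{i + 1}" for i in range(self.n_models)]


_SUPER_PATHWAYS = ["amino acid", "peptide", "lipid", "carbohydrate", "nucleotide"]


def simulate_metabolomics(
    design: ScreenDesign,
    seed: int,
    feature_names: list[str] | None = None,
    pathway_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy metabolite abundance table: metabolite, super_pathway, model,
    condition, replicate, sample, abundance.

    Parental replicates are lognormal(mu, sigma); mesenchymal replicates
    are lognormal(mu + ln FC, sigma) for planted features, FC=1 otherwise.
    The 20 standard amino acids are always included (annotated
    "amino acid") so the amino-acid panel has its inputs.
    """
    rng = np.random.default_rng(seed)
    if feature_names is None:
        named = list(TWENTY_AMINO_ACIDS)
        extra = [f"met{i:04d}" for i in range(design.n_features - len(named))]
        feature_names = named + extra
    if pathway_of is None:
        pathway_of = {}

    def pathway_for(idx: int, feat: str) -> str:
        if feat in pathway_of:
            return pathway_of[feat]
        if feat in TWENTY_AMINO_ACIDS:
            return "amino acid"
        return _SUPER_PATHWAYS[idx % len(_SUPER_PATHWAYS)]

    n_feat = len(feature_names)
    models = design.models
    conds = ["parental", "mesenchymal"]
    reps = np.arange(1, design.n_replicates + 1)
    mu = np.log(1000.0)
    # mean-shift cube: (feature, model, condition); mesenchymal gets ln FC
    shift = np.zeros((n_feat, len(models), 2))
    for fi, feat in enumerate(feature_names):
        fc = design.planted_effects.get(feat, 1.0)
        if fc != 1.0:
            for mi, model in enumerate(models):
                if model in design.model_restricted.get(feat, models):
                    shift[fi, mi, 1] = np.log(fc)
    vals = rng.lognormal(
        mu + shift[..., None], design.sigma,
        (n_feat, len(models), 2, design.n_replicates),
    )
    idx = pd.MultiIndex.from_product(
        [feature_names, models, conds, reps],
        names=["metabolite", "model", "condition", "replicate"],
    )
    df = pd.DataFrame({"abundance": vals.ravel()}, index=idx).reset_index()
    pathways = {f: pathway_for(i, f) for i, f in enumerate(feature_names)}
    df.insert(1, "super_pathway", df["metabolite"].map(pathways))
    df["sample"] = (
        df["model"] + "_" + df["condition"] + "_r" + df["replicate"].astype(str)
    )
    return df


@dataclass
class ExpressionData:
    """A log2 expression matrix (genes x samples) with sample annotations."""

    matrix: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, model, condition, replicate
    metabolism_genes: list[str]


def simulate_expression(
    design: ScreenDesign,
    seed: int,
    n_metabolism_genes: int = 200,
) -> ExpressionData:
    """Log2-scale expression matrix with PDK1..PDK4 present by name.

    Planted effects are fold-changes on the linear scale, applied as
    log2(FC) mean shifts in the mesenchymal condition.  A deterministic
    subset of genes (plus the PDK family) forms the metabolism gene set.
    """
    rng = np.random.default_rng(seed)
    pdk = ["PDK1", "PDK2", "PDK3", "PDK4"]
    n_other = design.n_features - len(pdk)
    genes = pdk + [f"GENE{i:05d}" for i in range(n_other)]
    sample_rows = []
    cols = {}
    for model in design.models:
        for cond in ("parental", "mesenchymal"):
            for rep in range(1, design.n_replicates + 1):
                name = f"{model}_{cond}_r{rep}"
                sample_rows.append(
                    {"sample": name, "model": model, "condition": cond, "replicate": rep}
                )
                shift = np.zeros(len(genes))
                if cond == "mesenchymal":
                    for gi, g in enumerate(genes):
                        fc = design.planted_effects.get(g)
                        if fc is not None and model in design.model_restricted.get(
                            g, design.models
                        ):
                            shift[gi] = np.log2(fc)
                cols[name] = 8.0 + shift + rng.normal(0.0, design.sigma, len(genes))
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    metabolism = pdk + [g for g in genes[4 : 4 + n_metabolism_genes - 4]]
    return ExpressionData(
        matrix=matrix, samples=pd.DataFrame(sample_rows), metabolism_genes=metabolism
    )


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSpec:
    """Exponential survival world with a median-split hazard effect.

    ``true_hr`` multiplies the baseline hazard in the low-expression
    stratum; censoring is an independent exponential clock.
    """

    n_patients: int = 150
    true_hr: float = 2.0
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.01  # censorings per month
    n_cohorts: int = 3

    def __post_init__(self) -> None:
        if self.true_hr <= 0:
            raise InvalidParameterError("true_hr must be > 0")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise InvalidParameterError("rates must be positive")


def simulate_survival_cohorts(spec: SurvivalSpec, seed: int) -> list[pd.DataFrame]:
    """One DataFrame per cohort: patient_id, time (months), event, expression.

    Expression is standard normal; the low stratum (expression <= cohort
    median) has hazard baseline*true_hr.  Observed time is the minimum of
    the event and censoring clocks.
    """
    rng = np.random.default_rng(seed)
    cohorts = []
    for c in range(spec.n_cohorts):
        expr = rng.standard_normal(spec.n_patients)
        low = expr <= np.median(expr)
        hazard = spec.baseline_hazard * np.where(low, spec.true_hr, 1.0)
        t_event = rng.exponential(1.0 / hazard)
        if spec.censor_rate > 0:
            t_cens = rng.exponential(1.0 / spec.censor_rate, spec.n_patients)
        else:
            t_cens = np.full(spec.n_patients, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        cohorts.append(
            pd.DataFrame(
                {
                    "cohort": f"cohort{c + 1}",
                    "patient_id": [f"c{c + 1}_p{i:04d}" for i in range(spec.n_patients)],
                    "time": time,
                    "event": event,
                    "expression": expr,
                }
            )
        )
    return cohorts
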