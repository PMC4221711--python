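"""Mass-isotopologue distribution (MID) core.

Turns raw isotopologue intensity vectors from a 13C tracing experiment
into natural-abundance-corrected MIDs and computes the fractional
contribution statistics used to read carbon flow: the M+k fraction of a
metabolite's pool is diagnostic of how much of that pool carries k tracer
carbons.  The glucose -> glutamate contribution, for example, is the M+2
glutamate fraction under U-13C6 glucose; dividing it by the M+3 pyruvate
fraction yields a proxy for relative PDH activity that is insensitive to
the labelled fraction of the upstream pyruvate pool.

Only carbon isotopes are modelled: each of the N-j unlabelled carbons of a
molecule with j tracer carbons independently carries a natural 13C with
probability ``p13`` (default 1.07%), giving a closed-form lower-triangular
binomial correction matrix.  Correction solves the resulting linear system
under a non-negativity constraint (NNLS) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import comb

from .errors import (
    DegenerateInputError,
    InvalidMeasurementError,
    InvalidParameterError,
)

#: Natural abundance of 13C used throughout unless overridden.
DEFAULT_P13 = 0.0107

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundSpec:
    """A compound identified by name and carbon count (glutamate 5, citrate 6, ...)."""

    name: str
    n_carbons: int

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise InvalidParameterError(
                f"{self.name}: n_carbons must be >= 1, got {self.n_carbons}"
            )


# Carbon counts for the compounds tracked by the first-turn TCA model.
COMPOUNDS = {
    "pyruvate": CompoundSpec("pyruvate", 3),
    "lactate": CompoundSpec("lactate", 3),
    "citrate": CompoundSpec("citrate", 6),
    "alpha-ketoglutarate": CompoundSpec("alpha-ketoglutarate", 5),
    "malate": CompoundSpec("malate", 4),
    "glutamate": CompoundSpec("glutamate", 5),
}


@dataclass(frozen=True)
class RawIntensityVector:
    """Measured isotopologue intensities for one compound in one sample.

    ``intensities[k]`` is the signal at mass shift M+k, k = 0..n_carbons.
    """

    compound: CompoundSpec
    sample_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.shape != (self.compound.n_carbons + 1,):
            raise InvalidParameterError(
                f"{self.compound.name}/{self.sample_id}: expected "
                f"{self.compound.n_carbons + 1} intensities, got {arr.shape}"
            )
        if np.any(arr < 0):
            raise InvalidMeasurementError(
                f"{self.compound.name}/{self.sample_id}: negative intensity"
            )
        if not np.any(arr > 0):
            raise DegenerateInputError(
                f"{self.compound.name}/{self.sample_id}: all-zero intensities"
            )


@dataclass(frozen=True)
class MID:
    """A mass-isotopologue distribution: fractions over mass shifts 0..N."""

    compound: CompoundSpec
    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", arr)
        if arr.shape != (self.compound.n_carbons + 1,):
            raise InvalidParameterError(
                f"{self.compound.name}: MID length {arr.shape} != N+1"
            )
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise InvalidParameterError(f"{self.compound.name}: fractions outside [0,1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"{self.compound.name}: fractions sum to {arr.sum()}, not 1"
            )


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular natural-abundance smearing matrix.

    ``entries[i, j]`` is the probability that a molecule with j tracer
    carbons is observed at mass shift i; columns are probability vectors.
    """

    n_carbons: int
    p13: float
    entries: np.ndarray


@dataclass(frozen=True)
class SeahorseMeasurement:
    """One extracellular-flux well: proton production and O2 consumption rates."""

    sample_id: str
    condition: str
    ppr: float  # pmol H+/min
    ocr: float  # pmol O2/min

    def __post_init__(self) -> None:
        if self.ppr <= 0 or self.ocr <= 0:
            raise InvalidMeasurementError(
                f"{self.sample_id}: PPR and OCR must be positive "
                f"(got ppr={self.ppr}, ocr={self.ocr})"
            )


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison: means, SEMs, fold-change (b/a) and Student t-test."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass(frozen=True)
class FluxParams:
    """Ground-truth fractions of the first-turn TCA labelling model.

    f_pyr  -- fraction of the pyruvate pool that is tracer-derived
              (M+3 under U-13C6 glucose).
    g_pdh  -- fraction of citrate acetyl units supplied by labelled
              pyruvate via PDH; the relative-PDH-activity dial.
    q_gln  -- fraction of the glutamate pool derived directly from
              glutamine (M+5 under U-13C5 glutamine).
    d_lac  -- dilution of lactate labelling relative to pyruvate.
    """

    f_pyr: float
    g_pdh: float
    q_gln: float
    d_lac: float = 0.0
    noise_cv: float = 0.0
    ppr_true: float = 100.0
    ocr_true: float = 50.0

    def __post_init__(self) -> None:
        for name in ("f_pyr", "g_pdh", "q_gln", "d_lac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0,1]")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.ppr_true <= 0 or self.ocr_true <= 0:
            raise InvalidParameterError("ppr_true and ocr_true must be positive")


# ---------------------------------------------------------------------------
# Natural-abundance correction
# ---------------------------------------------------------------------------


def build_correction_matrix(n_carbons: int, p13: float = DEFAULT_P13) -> CorrectionMatrix:
    """Closed-form binomial smearing matrix for an N-carbon compound.

    entry[i, j] = C(N-j, i-j) * p13**(i-j) * (1-p13)**(N-i) for i >= j:
    of the N-j carbons not supplied by the tracer, i-j happen to be 13C
    by natural abundance.  Every column sums to 1.
    """
    if not isinstance(n_carbons, (int, np.integer)) or n_carbons < 1 or n_carbons > 50:
        raise InvalidParameterError(f"n_carbons must be in 1..50, got {n_carbons}")
    if not 0.0 <= p13 < 0.5:
        raise InvalidParameterError(f"p13 must be in [0, 0.5), got {p13}")
    n = int(n_carbons)
    entries = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        # column j: binomial(N-j, p13) over the extra shift i-j, written in
        # closed form (stable down to p13 = 0, unlike the pmf special function)
        k = np.arange(n + 1 - j, dtype=float)
        entries[j:, j] = comb(n - j, k) * np.power(p13, k) * np.power(1.0 - p13, n - j - k)
    return CorrectionMatrix(n_carbons=n, p13=p13, entries=entries)


def correct_natural_abundance(
    raw: RawIntensityVector,
    p13: float = DEFAULT_P13,
    method: str = "nnls",
) -> MID:
    """Remove natural 13C contributions so residual labelling reflects tracer only.

    method='nnls' minimises ||C x - raw/sum(raw)|| s.t. x >= 0 (default);
    method='solve_clip' does the plain triangular solve and clips negatives.
    Either way the result is renormalised to sum to 1.
    """
    cm = build_correction_matrix(raw.compound.n_carbons, p13)
    y = raw.intensities / raw.intensities.sum()
    if method == "nnls":
        x, _ = optimize.nnls(cm.entries, y)
    elif method == "solve_clip":
        x = np.linalg.solve(cm.entries, y)
        x = np.clip(x, 0.0, None)
    else:
        raise InvalidParameterError(f"unknown correction method {method!r}")
    total = x.sum()
    if total <= 0:
        raise DegenerateInputError(
            f"{raw.compound.name}/{raw.sample_id}: correction produced a zero vector"
        )
    return MID(compound=raw.compound, fractions=x / total)


def normalize_mid(raw: RawIntensityVector) -> MID:
    """Fractions = intensities / total pool, with no isotope correction."""
    total = raw.intensities.sum()
    if total <= 0:
        raise DegenerateInputError(f"{raw.compound.name}: zero total intensity")
    return MID(compound=raw.compound, fractions=raw.intensities / total)


# ---------------------------------------------------------------------------
# Fractional-contribution statistics
# ---------------------------------------------------------------------------


def fractional_enrichment(mid: MID, k: int) -> float:
    """The M+k fraction of the compound's total pool."""
    if not 0 <= k <= mid.compound.n_carbons:
        raise IndexError(
            f"k={k} outside 0..{mid.compound.n_carbons} for {mid.compound.name}"
        )
    return float(mid.fractions[k])


def contribution_ratio(mid_num: MID, k_num: int, mid_den: MID, k_den: int) -> float:
    """Ratio of two fractional enrichments.

    With numerator (glutamate, M+2) and denominator (pyruvate, M+3) under a
    U-13C6 glucose tracer this is the PDH-activity proxy: the glucose ->
    glutamate contribution normalised by how labelled pyruvate itself is.
    """
    den = fractional_enrichment(mid_den, k_den)
    if den <= 0:
        raise DegenerateInputError("denominator enrichment is zero")
    return fractional_enrichment(mid_num, k_num) / den


@dataclass(frozen=True)
class RecoveredFluxParams:
    """Point estimates of (g_pdh, f_pyr, q_gln) from two tracer arms."""

    g_pdh: float
    f_pyr: float
    q_gln: float


def recover_flux_params(
    pyruvate_glc: MID,
    glutamate_glc: MID,
    glutamate_gln: MID,
) -> RecoveredFluxParams:
    """Invert the first-turn labelling model from paired tracer arms.

    f_pyr is read directly as the pyruvate M+3 fraction (glucose arm),
    q_gln as the glutamate M+5 fraction (glutamine arm), and g_pdh as the
    glutamate-M+2 / pyruvate-M+3 contribution ratio divided by the
    unlabelled-glutamine dilution (1 - q_gln), clipped to [0, 1].
    """
    f_pyr = fractional_enrichment(pyruvate_glc, 3)
    q_gln = fractional_enrichment(glutamate_gln, 5)
    if f_pyr <= 0:
        raise DegenerateInputError("pyruvate M+3 fraction is zero; arms unlabeled?")
    if q_gln >= 1:
        raise DegenerateInputError("glutamate M+5 fraction is 1; no glucose-derived pool")
    ratio = contribution_ratio(glutamate_glc, 2, pyruvate_glc, 3)
    g_pdh = float(np.clip(ratio / (1.0 - q_gln), 0.0, 1.0))
    return RecoveredFluxParams(g_pdh=g_pdh, f_pyr=f_pyr, q_gln=q_gln)


# ---------------------------------------------------------------------------
# Group comparison (Student t, as in the source study's statistics)
# ---------------------------------------------------------------------------


def student_t_compare(a, b, welch: bool = False) -> ComparisonResult:
    """Two-sample two-tailed t-test with fold-change mean(b)/mean(a).

    Pooled-variance Student t by default (df = n_a + n_b - 2); Welch's
    unequal-variance variant behind ``welch=True``.  Zero pooled variance
    with equal means gives t=0, p=1; with unequal means p=0 flagged
    degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs >= 2 observations")
    mean_a, mean_b = a.mean(), b.mean()
    sem_a = a.std(ddof=1) / np.sqrt(a.size)
    sem_b = b.std(ddof=1) / np.sqrt(b.size)
    fc = mean_b / mean_a if mean_a != 0 else np.inf
    # t is oriented a-minus-b; fold_change is b-over-a
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_a == mean_b:
            t_stat, p, degen = 0.0, 1.0, False
        else:
            t_stat, p, degen = -np.inf if mean_b > mean_a else np.inf, 0.0, True
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p, degen = float(t_stat), float(p), False
    return ComparisonResult(
        mean_a=float(mean_a), mean_b=float(mean_b),
        sem_a=float(sem_a), sem_b=float(sem_b),
        fold_change=float(fc), t_stat=t_stat, p_value=p,
        n_a=int(a.size), n_b=int(b.size), degenerate=degen,
    )


def glycolysis_oxphos_ratio(
    measurements: list[SeahorseMeasurement],
    condition_a: str = "parental",
    condition_b: str = "mesenchymal",
) -> dict:
    """Per-condition PPR/OCR (glycolysis/OXPHOS proxy) with a t-test between conditions.

    Returns {'per_condition': {condition: (mean, sem, n)},
             'comparison': ComparisonResult of condition_b vs condition_a}.
    """
    ratios: dict[str, list[float]] = {}
    for m in measurements:
        ratios.setdefault(m.condition, []).append(m.ppr / m.ocr)
    for cond, vals in ratios.items():
        if len(vals) < 2:
            raise InvalidParameterError(f"condition {cond!r} has < 2 wells")
    per_condition = {
        cond: (
            float(np.mean(v)),
            float(np.std(v, ddof=1) / np.sqrt(len(v))),
            len(v),
        )
        for cond, v in ratios.items()
    }
    comparison = None
    if condition_a in ratios and condition_b in ratios:
        comparison = student_t_compare(ratios[condition_a], ratios[condition_b])
    return {"per_condition": per_condition, "comparison": comparison}
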